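"""Self-contained synthetic circRNA loci for end-to-end testing.

The generator emits a multi-transcript gene on a single reference sequence
with a backsplice-competent exon block, flanking introns carrying planted
reverse-complementary repeats (optionally annotated with SINE-like
intervals), a canonical AG acceptor that can be mutated to TC, and a
planted cryptic AG downstream of it. One deterministic pseudo-random
stream (numpy PCG64, seeded from ``spec.seed``) drives every choice, so
fixtures are byte-stable. Planted mismatches sit at evenly spaced
positions, making identities exact and reproducible.

Introns are canonical (begin GT, end AG); genes are emitted on the +
strand, and :func:`mirror_bundle` produces the reverse-complemented -
strand twin used by strand-handling tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from pathlib import Path

from . import io as cio
from .locus import CircDef, LocusModel, TranscriptModel
from .seqs import DNA, random_dna, revcomp

# recipe exon: base exon index, optional 5'/3' extension into the adjacent
# intron (alternative TSS / splice sites), genomic + frame
ExonRef = tuple[int, int, int]


@dataclass(frozen=True)
class TranscriptRecipe:
    transcript_id: str
    exons: tuple  # ints or (index, ext5, ext3) triples
    coding: bool = False
    canonical: bool = False

    def refs(self) -> list[ExonRef]:
        out = []
        for e in self.exons:
            out.append((e, 0, 0) if isinstance(e, int) else tuple(e))
        return out


def default_recipes() -> tuple[TranscriptRecipe, ...]:
    """Six splice variants mirroring a Tulp4-like locus around circ exons 2-3.

    The canonical transcript starts at an alternative TSS 60 nt upstream of
    the circ acceptor, so it shares the circ sequence exonically without
    using the backsplice SA (which is internal to its first exon); two
    non-coding minor variants splice into that SA; two transcripts hold the
    circle only as intron. Overlap classes: exonic x4, intronic x2.
    """
    return (
        TranscriptRecipe("TX-201", ((2, 60, 0), 3, 4, 5, 6), coding=True, canonical=True),
        TranscriptRecipe("TX-202", (1, 2, 3, 4)),
        TranscriptRecipe("TX-203", (0, 2, 3)),
        TranscriptRecipe("TX-204", (3, 4, 5)),
        TranscriptRecipe("TX-205", (1, 4), coding=True),
        TranscriptRecipe("TX-206", (0, 5, 6), coding=True),
    )


PlantedRcm = tuple[int, float, int, int]  # (length, identity, up_offset, down_offset)


@dataclass(frozen=True)
class SyntheticLocusSpec:
    seed: int
    n_exons: int = 7
    exon_lengths: tuple[int, ...] = (250, 180, 150, 160, 140, 190, 320)
    intron_lengths: tuple[int, ...] = (800, 2000, 500, 2000, 600, 700)
    gc_content: float = 0.42
    circ_exon_range: tuple[int, int] = (2, 3)
    planted_rcms: tuple[PlantedRcm, ...] = ()
    plant_sine_bed: bool = True
    cryptic_ag_offset: int = 9
    transcript_recipes: tuple[TranscriptRecipe, ...] = field(default_factory=default_recipes)
    flank_length: int = 600
    exon_sequence_overrides: tuple[tuple[int, str], ...] = ()
    # keep the last N nt of the upstream intron (before its terminal AG)
    # free of ATG, so an alternative first exon extending over the acceptor
    # cannot gain a spurious upstream start codon
    atg_free_acceptor_upstream: int = 0
    chrom: str = "chrSYN"
    gene_id: str = "SYNGENE"

    def validate(self) -> None:
        if self.n_exons < 3:
            raise ValueError("need at least 3 exons")
        if len(self.exon_lengths) != self.n_exons:
            raise ValueError("exon_lengths inconsistent with n_exons")
        if len(self.intron_lengths) != self.n_exons - 1:
            raise ValueError("intron_lengths inconsistent with n_exons")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0,1]")
        c0, c1 = self.circ_exon_range
        if not (0 < c0 <= c1 < self.n_exons - 1):
            raise ValueError("circularized block must be internal to the gene "
                             "(flanking introns on both sides)")
        if self.cryptic_ag_offset < 0 or self.cryptic_ag_offset + 2 > self.exon_lengths[c0]:
            raise ValueError("cryptic AG lands outside the first circularized exon")
        canon = [r.transcript_id for r in self.transcript_recipes if r.canonical]
        if len(canon) != 1:
            raise ValueError(f"exactly one canonical transcript required, got {canon}")
        for intron_idx in (c0 - 1, c1):
            plants = [(off, off + ln) for (ln, ident, up, down) in self.planted_rcms
                      for off in ([up] if intron_idx == c0 - 1 else [down])]
            plants.sort()
            for (s, e) in plants:
                if s < 2 or e > self.intron_lengths[intron_idx] - 2:
                    raise ValueError("planted RCM does not fit inside its intron "
                                     "(GT/AG termini must stay intact)")
            for (s1, e1), (s2, e2) in zip(plants, plants[1:]):
                if s2 < e1:
                    raise ValueError("overlapping planted RCMs")
        for ln, ident, _, _ in self.planted_rcms:
            if not 0.0 < ident <= 1.0:
                raise ValueError("RCM identity must be in (0,1]")
            if ln < 4:
                raise ValueError("planted RCM too short")


@dataclass(frozen=True)
class RcmTruth:
    up_interval: tuple[int, int]    # genomic, upstream (transcription) intron
    down_interval: tuple[int, int]
    length: int
    identity: float
    n_mismatches: int


@dataclass
class SyntheticLocusBundle:
    spec: SyntheticLocusSpec
    genome_sequence: str
    gene: LocusModel
    circ: CircDef
    rcm_truth: list[RcmTruth]
    repeat_intervals: list[tuple[int, int, str]]
    ct_table: pd.DataFrame
    gene_exons: list[tuple[int, int]]          # base exon intervals
    intron_intervals: list[tuple[int, int]]
    up_intron: tuple[int, int]                 # flanking introns, genomic
    down_intron: tuple[int, int]
    mirnas: dict[str, str] = field(default_factory=dict)

    @property
    def strand(self) -> str:
        return self.gene.strand

    def _seq(self, interval: tuple[int, int]) -> str:
        s, e = interval
        seq = self.genome_sequence[s:e]
        return seq if self.strand == "+" else revcomp(seq)

    def up_intron_seq(self) -> str:
        return self._seq(self.up_intron)

    def down_intron_seq(self) -> str:
        return self._seq(self.down_intron)

    def _local(self, interval: tuple[int, int], intron: tuple[int, int]) -> tuple[int, int]:
        s, e = interval
        if self.strand == "+":
            return s - intron[0], e - intron[0]
        return intron[1] - e, intron[1] - s

    def rcm_truth_local(self) -> list[RcmTruth]:
        """Planted RCMs in the intron-local frames used by find_rcm."""
        return [replace(t,
                        up_interval=self._local(t.up_interval, self.up_intron),
                        down_interval=self._local(t.down_interval, self.down_intron))
                for t in self.rcm_truth]

    def repeats_local(self) -> tuple[list, list]:
        """Repeat intervals in intron-local coordinates (up, down)."""
        up, down = [], []
        for s, e, name in self.repeat_intervals:
            for intron, acc in ((self.up_intron, up), (self.down_intron, down)):
                if s < intron[1] and intron[0] < e:
                    ls, le = self._local((max(s, intron[0]), min(e, intron[1])), intron)
                    acc.append((ls, le, name))
        return up, down

    def transcript_mrna(self, transcript_id: str) -> str:
        tx = self.gene.transcript(transcript_id)
        return "".join(self._seq(e) for e in tx.exons)

    def linear_mrnas(self) -> dict[str, str]:
        return {t.transcript_id: self.transcript_mrna(t.transcript_id)
                for t in self.gene.transcripts}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA/GFF3/BED/TSV fixtures plus a provenance manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "locus.fa",
            "gff3": outdir / "locus.gff3",
            "circ_bed": outdir / "circ.bed",
            "repeats_bed": outdir / "repeats.bed",
            "ct_tsv": outdir / "ct.tsv",
            "manifest": outdir / "manifest.yaml",
        }
        cio.write_fasta({self.spec.chrom: self.genome_sequence}, paths["fasta"])
        cio.write_gff3(self.gene, paths["gff3"])
        cio.write_circ_bed(self.circ, paths["circ_bed"])
        cio.write_bed6(self.repeat_intervals, self.spec.chrom, self.strand,
                       paths["repeats_bed"])
        self.ct_table.to_csv(paths["ct_tsv"], sep="\t", index=False)
        if self.mirnas:
            paths["mirna_fasta"] = outdir / "mirna.fa"
            cio.write_fasta(self.mirnas, paths["mirna_fasta"])
        manifest = {
            "seed": self.spec.seed,
            "n_exons": self.spec.n_exons,
            "exon_lengths": list(self.spec.exon_lengths),
            "intron_lengths": list(self.spec.intron_lengths),
            "gc_content": self.spec.gc_content,
            "circ_exon_range": list(self.spec.circ_exon_range),
            "planted_rcms": [list(p) for p in self.spec.planted_rcms],
            "cryptic_ag_offset": self.spec.cryptic_ag_offset,
            "strand": self.strand,
        }
        paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=True))
        return paths


# deterministic base flip used for planted mismatches: always changes the base
_FLIP = {"A": "C", "C": "A", "G": "T", "T": "G"}


def _evenly_spaced(length: int, n: int) -> list[int]:
    return sorted({math.floor((k + 0.5) * length / n) for k in range(n)})


def make_locus(spec: SyntheticLocusSpec) -> SyntheticLocusBundle:
    """Build the synthetic locus bundle; deterministic for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    c0, c1 = spec.circ_exon_range
    overrides = dict(spec.exon_sequence_overrides)

    exon_seqs: list[str] = []
    for i, ln in enumerate(spec.exon_lengths):
        if i in overrides:
            seq = overrides[i].upper()
            if len(seq) != ln:
                raise ValueError(f"override for exon {i} has length {len(seq)}, "
                                 f"expected {ln}")
        elif i == c0:
            # acceptor exon: AG-free prefix, then the planted cryptic AG
            off = spec.cryptic_ag_offset
            prefix = random_dna(rng, off, gc, forbid="AG")
            seq = prefix + "AG" + random_dna(rng, ln - off - 2, gc)
        else:
            seq = random_dna(rng, ln, gc)
        exon_seqs.append(seq)
    if c0 in overrides:
        off = spec.cryptic_ag_offset
        ex = exon_seqs[c0]
        if ex[off:off + 2] != "AG" or "AG" in ex[:off + 1]:
            raise ValueError("exon override violates the planted-cryptic-AG layout")

    intron_seqs: list[str] = []
    for i, ln in enumerate(spec.intron_lengths):
        scrub = spec.atg_free_acceptor_upstream if i == c0 - 1 else 0
        if scrub > ln - 4:
            raise ValueError("ATG-free acceptor-upstream zone exceeds the intron")
        body = random_dna(rng, ln - 4 - scrub, gc)
        while scrub:
            tail = random_dna(rng, scrub, gc, forbid="ATG")
            if "ATG" not in (body[-2:] + tail + "AG" + exon_seqs[c0][:2]):
                body += tail
                break
        intron_seqs.append("GT" + body + "AG")

    rcm_truth_raw = []  # (intron-local up, intron-local down, length, identity, mism)
    up_len = spec.intron_lengths[c0 - 1]
    for (ln, ident, up_off, down_off) in spec.planted_rcms:
        if spec.atg_free_acceptor_upstream and \
                up_off + ln > up_len - 2 - spec.atg_free_acceptor_upstream:
            raise ValueError("planted RCM reaches into the ATG-free acceptor zone")
        seg = random_dna(rng, ln, gc)
        n_mis = round(ln * (1.0 - ident))
        down_seg = list(revcomp(seg))
        for pos in _evenly_spaced(ln, n_mis) if n_mis else []:
            down_seg[pos] = _FLIP[down_seg[pos]]
        down_seg = "".join(down_seg)
        up = intron_seqs[c0 - 1]
        intron_seqs[c0 - 1] = up[:up_off] + seg + up[up_off + ln:]
        dn = intron_seqs[c1]
        intron_seqs[c1] = dn[:down_off] + down_seg + dn[down_off + ln:]
        achieved = 1.0 - n_mis / ln
        rcm_truth_raw.append(((up_off, up_off + ln), (down_off, down_off + ln),
                              ln, achieved, n_mis))

    flank5 = random_dna(rng, spec.flank_length, gc)
    flank3 = random_dna(rng, spec.flank_length, gc)
    parts, exon_iv, intron_iv = [flank5], [], []
    pos = len(flank5)
    for i in range(spec.n_exons):
        exon_iv.append((pos, pos + len(exon_seqs[i])))
        parts.append(exon_seqs[i])
        pos += len(exon_seqs[i])
        if i < spec.n_exons - 1:
            intron_iv.append((pos, pos + len(intron_seqs[i])))
            parts.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    genome = "".join(parts) + flank3

    up_intron, down_intron = intron_iv[c0 - 1], intron_iv[c1]
    rcm_truth = [RcmTruth((up_intron[0] + us, up_intron[0] + ue),
                          (down_intron[0] + ds, down_intron[0] + de), ln, ident, mis)
                 for (us, ue), (ds, de), ln, ident, mis in rcm_truth_raw]

    transcripts = []
    for recipe in spec.transcript_recipes:
        exons = []
        for idx, ext5, ext3 in recipe.refs():
            if not 0 <= idx < spec.n_exons:
                raise ValueError(f"recipe references exon {idx} outside the gene")
            s, e = exon_iv[idx]
            s -= ext5
            e += ext3
            if idx > 0 and s < exon_iv[idx - 1][1]:
                raise ValueError("exon 5' extension reaches the previous exon")
            if idx < spec.n_exons - 1 and e > exon_iv[idx + 1][0]:
                raise ValueError("exon 3' extension reaches the next exon")
            for t in rcm_truth:
                for (ps, pe) in (t.up_interval, t.down_interval):
                    if s < pe and ps < e and (ext5 or ext3):
                        raise ValueError("exon extension covers a planted RCM")
            exons.append((s, e))
        transcripts.append(TranscriptModel(recipe.transcript_id, tuple(exons),
                                           recipe.coding, recipe.canonical))
    canonical = next(r.transcript_id for r in spec.transcript_recipes if r.canonical)
    gene = LocusModel(spec.gene_id, "+", spec.chrom, tuple(transcripts), canonical)

    chain = tuple(exon_iv[i] for i in range(c0, c1 + 1))
    circ = CircDef(spec.chrom, "+", chain[0][0], chain[-1][1], chain)
    for t in gene.transcripts:
        span = t.span
        if not (gene.span[0] <= span[0] and span[1] <= gene.span[1]):
            raise ValueError("transcript outside gene span")

    repeats = []
    if spec.plant_sine_bed:
        for k, t in enumerate(rcm_truth, 1):
            for side, (s, e) in (("up", t.up_interval), ("down", t.down_interval)):
                intron = up_intron if side == "up" else down_intron
                repeats.append((max(s - 15, intron[0]), min(e + 15, intron[1]),
                                f"SINE_B1_{k}{side[0]}"))

    ct = make_ct_table(int(rng.integers(2 ** 31)), DEFAULT_EXPRESSION, noise_sd=0.25)

    return SyntheticLocusBundle(
        spec=spec, genome_sequence=genome, gene=gene, circ=circ,
        rcm_truth=rcm_truth, repeat_intervals=repeats, ct_table=ct,
        gene_exons=exon_iv, intron_intervals=intron_iv,
        up_intron=up_intron, down_intron=down_intron)


# ---------------------------------------------------------------------------
# Ct tables

# study conditions: in the knockout (CD) condition the circle drops to 34.6%
# of wild type (a 65.4% knockdown) while the linear isoform is unchanged
DEFAULT_EXPRESSION = {
    "WT": {"circ": 3.0, "linear": 4.0, "HK1": 6.0, "HK2": 5.0},
    "CD": {"circ": 3.0 + math.log2(0.346), "linear": 4.0, "HK1": 6.0, "HK2": 5.0},
}


def make_ct_table(seed: int, true_log2_expr: dict, noise_sd: float = 0.0,
                  n_samples: int = 3, baseline: float = 30.0) -> pd.DataFrame:
    """Simulated qPCR Ct table: Ct = baseline - log2(expression) + noise.

    ``true_log2_expr`` maps condition -> {target: log2 expression} (or is a
    flat target map, treated as a single condition). Both housekeepers HK1
    and HK2 must be present. Reproducible for a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if true_log2_expr and not isinstance(next(iter(true_log2_expr.values())), dict):
        true_log2_expr = {"COND": true_log2_expr}
    rng = np.random.default_rng(seed)
    rows = []
    for cond, expr in true_log2_expr.items():
        for hk in ("HK1", "HK2"):
            if hk not in expr:
                raise ValueError(f"housekeeper {hk} missing from condition {cond}")
        for i in range(1, n_samples + 1):
            sample = f"{cond}_{i}"
            for target, log2e in expr.items():
                ct = baseline - log2e + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                rows.append((sample, cond, target, round(float(ct), 4)))
    return pd.DataFrame(rows, columns=["sample", "condition", "target", "ct"])


# ---------------------------------------------------------------------------
# mirrored (- strand) bundle


def mirror_bundle(b: SyntheticLocusBundle) -> SyntheticLocusBundle:
    """The reverse-complemented twin: same biology on the - strand."""
    L = len(b.genome_sequence)

    def miv(iv):
        return (L - iv[1], L - iv[0])

    transcripts = tuple(
        TranscriptModel(t.transcript_id, tuple(miv(e) for e in t.exons),
                        t.coding, t.is_canonical)
        for t in b.gene.transcripts)
    gene = LocusModel(b.gene.gene_id, "-", b.gene.sequence_ref, transcripts,
                      b.gene.canonical_id)
    chain = tuple(miv(e) for e in b.circ.exon_chain)
    circ = CircDef(b.circ.chrom, "-", L - b.circ.acceptor_pos,
                   L - b.circ.donor_pos, chain)
    truth = [replace(t, up_interval=miv(t.up_interval),
                     down_interval=miv(t.down_interval)) for t in b.rcm_truth]
    repeats = [(L - e, L - s, name) for s, e, name in b.repeat_intervals]
    return SyntheticLocusBundle(
        spec=b.spec, genome_sequence=revcomp(b.genome_sequence), gene=gene,
        circ=circ, rcm_truth=truth, repeat_intervals=repeats,
        ct_table=b.ct_table.copy(),
        gene_exons=[miv(e) for e in b.gene_exons],
        intron_intervals=[miv(i) for i in b.intron_intervals],
        up_intron=miv(b.up_intron), down_intron=miv(b.down_intron),
        mirnas=dict(b.mirnas))


def rflp_fixture(seed: int = 0, amplicon_len: int = 646,
                 cut_at: int = 446) -> tuple[str, str]:
    """Synthetic genotyping amplicon pair for Dde I RFLP (CTNAG, C^TNAG).

    The wild-type amplicon has no Dde I site; the edited allele carries an
    AG->TC change that creates exactly one site cutting ``cut_at`` bp in, so
    the digest yields one full-length fragment for WT and two fragments
    (cut_at + remainder) for the edited allele. The real genomic sequence is
    not modelled — only the fragment-length pattern.
    """
    from .locus import apply_mutations, digest_fragments
    rng = np.random.default_rng(seed)
    core_at = cut_at - 1  # motif start; cut falls one base into the motif
    while True:
        seq = random_dna(rng, amplicon_len, 0.45)
        wt = seq[:core_at] + "CAGAG" + seq[core_at + 5:]
        cd = apply_mutations(wt, [(core_at + 1, "AG", "TC")])  # -> CTCAG site
        if digest_fragments(wt) == (amplicon_len,) and \
                digest_fragments(cd) == (cut_at, amplicon_len - cut_at):
            return wt, cd


# ---------------------------------------------------------------------------
# the Tulp4-mimic fixture

CIRC_TAIL = "NLRGHNSESCK" + "SPSRTFQS"   # aa 77-95 of the mimic ORF
SHARED_PREFIX_AA = 84                    # aa 1-84 shared with the linear protein

# synonymous codon tables restricted to AG-free choices where needed
_CODONS = {
    "A": ["GCT", "GCC", "GCA"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
    "E": ["GAA"], "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC"], "K": ["AAA"],
    "L": ["CTT", "CTC", "CTA", "TTG"], "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCA", "CCC"], "Q": ["CAA"], "R": ["CGT", "CGC", "CGA"],
    "S": ["TCT", "TCC", "TCA"], "T": ["ACT", "ACC", "ACA"],
    "V": ["GTT", "GTC", "GTA"], "W": ["TGG"], "Y": ["TAT", "TAC"],
}


def _encode(rng: np.random.Generator, peptide: str) -> str:
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in peptide)


@dataclass(frozen=True)
class TulpMimic:
    bundle: SyntheticLocusBundle
    circ_orf_start: int        # circle coordinate of the engineered ATG
    circ_peptide: str          # the 95-aa junction-spanning product
    shared_prefix_aa: int
    divergent_peptides: tuple[str, ...]
    primers: tuple[str, str]   # divergent RT-qPCR pair on the circle


def tulp4_mimic_bundle(seed: int = 0) -> TulpMimic:
    """A locus engineered to exhibit every hallmark of the studied gene.

    The circularized exons 2-3 (150 + 160 nt, a 310-nt circle) carry a
    95-aa ORF starting 58 nt into the circle: its first 84 aa read straight
    through to the junction and are shared with the canonical linear
    protein, while aa 85-95 (…SCK + SPSRTFQS) are encoded by the circle
    wrap-around and are circle-specific — the layout behind the
    NLRGHNSESCK / GHNSESCK / SPSRTFQS discriminative tryptic peptides. The
    cryptic AG sits 9 nt into the acceptor exon; flanking 2-kb introns
    carry five planted RCMs of graded length.
    """
    rng = np.random.default_rng(seed)
    aas = [aa for aa in _CODONS if aa != "M"]  # no internal Met: one in-frame start
    x75 = "".join(aas[rng.integers(len(aas))] for _ in range(75))
    peptide = "M" + x75 + CIRC_TAIL
    assert len(peptide) == 95

    shared = _encode(rng, peptide[:SHARED_PREFIX_AA])      # 252 nt, aa 1-84
    # circle-specific tail, aa 85-95 (SCK + SPSRTFQS); the first four codons
    # are fixed to give an AG-free 9-nt exon prefix followed by the planted
    # cryptic AG (AGT = Ser-88)
    assert peptide[84:88] == "SCKS"
    tail_fixed = "TCT" + "TGC" + "AAA" + "AGT"             # S C K S
    tail_rest = _encode(rng, peptide[88:])                 # P S R T F Q S
    tail = tail_fixed + tail_rest
    assert len(tail) == 33

    while True:
        filler = random_dna(rng, 22, 0.45, forbid="ATG")
        exon2 = tail + "TAA" + filler + shared[:92]
        if "ATG" not in exon2[30:60]:
            break
    exon3 = shared[92:252]
    assert len(exon2) == 150 and len(exon3) == 160
    # linear translation continues into exon 4: pin its first codon to Gly so
    # the linear protein diverges from the circle product at exactly aa 85
    exon4 = "GGT" + random_dna(rng, 137, 0.45)

    spec = SyntheticLocusSpec(
        seed=seed + 1,
        planted_rcms=((300, 1.0, 40, 60), (220, 0.95, 420, 480),
                      (150, 0.92, 760, 840), (100, 0.88, 1100, 1200),
                      (60, 0.87, 1450, 1500)),
        cryptic_ag_offset=9,
        exon_sequence_overrides=((2, exon2), (3, exon3), (4, exon4)),
        atg_free_acceptor_upstream=60,
    )
    bundle = make_locus(spec)

    # divergent primer pair reading outward across the junction
    from .circle import build_circle
    circ_seq = build_circle(bundle.genome_sequence, bundle.circ).sequence
    fwd = circ_seq[240:260]
    rev = revcomp(circ_seq[20:40])

    # one miRNA with a junction-spanning 8mer site, one without any site
    L = len(circ_seq)
    site7 = circ_seq[L - 1:] + circ_seq[:6]    # followed by circ_seq[6] == 'A'
    assert circ_seq[6] == "A"
    mir_planted = "T" + revcomp(site7) + random_dna(rng, 14, 0.5)
    mirnas = {"syn-miR-junction": mir_planted}
    while True:
        decoy = random_dna(rng, 22, 0.5)
        if revcomp(decoy[1:7]) not in circ_seq + circ_seq[:8]:
            mirnas["syn-miR-decoy"] = decoy
            break
    bundle.mirnas = mirnas

    return TulpMimic(
        bundle=bundle,
        circ_orf_start=58,
        circ_peptide=peptide,
        shared_prefix_aa=SHARED_PREFIX_AA,
        divergent_peptides=("NLRGHNSESCK", "GHNSESCK", "SPSRTFQS"),
        primers=(fwd, rev),
    )
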