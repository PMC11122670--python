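"""Junction-centric analyses on the circularized exon chain.

The circle is linearized starting at the acceptor-side first base, so the
backsplice junction — the circle-specific seam between the donor-side last
base and the acceptor-side first base — sits at the 0/length boundary.
Every coordinate reported here is a position on that linearization; all
results are rotation-invariant up to the corresponding coordinate shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .locus import CircDef
from .seqs import gc_fraction, normalize_nt, revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class CircleSeq:
    sequence: str
    junction_index: int = 0  # junction sits between index length-1 and 0

    @property
    def length(self) -> int:
        return len(self.sequence)

    def window(self, start: int, length: int) -> str:
        """Sequence of ``length`` nt starting at ``start``, wrapping the junction."""
        s2 = self.sequence + self.sequence
        start %= self.length
        if length > self.length:
            raise ValueError("window longer than the circle")
        return s2[start:start + length]


def build_circle(genome: str | dict[str, str], circ: CircDef) -> CircleSeq:
    """Concatenate the backspliced exon chain 5'->3' into a CircleSeq.

    For a - strand circle the chain exons (transcription order = descending
    genomic) are reverse-complemented. The linearization starts at the
    acceptor-side first transcribed base.
    """
    seq = genome[circ.chrom] if isinstance(genome, dict) else genome
    parts = []
    for s, e in circ.exon_chain:
        if not (0 <= s < e <= len(seq)):
            raise ValueError(f"exon ({s},{e}) outside the locus sequence")
        exon = seq[s:e]
        parts.append(exon if circ.strand == "+" else revcomp(exon))
    return CircleSeq("".join(parts))


def junction_window(circle: CircleSeq, flank: int) -> str:
    """The 2*flank nt centered on the backsplice junction (circle-specific)."""
    if flank > circle.length:
        raise ValueError("flank exceeds circle length")
    if flank <= 0:
        raise ValueError("flank must be positive")
    return circle.sequence[-flank:] + circle.sequence[:flank]


# ---------------------------------------------------------------------------
# junction-spanning shRNA / probe design


@dataclass(frozen=True)
class JunctionOligo:
    sequence: str       # target site on the circle, sense orientation
    circ_offset: int    # start position on the linearization (may be > junction)
    left_arm: int       # nt upstream (donor side) of the junction
    right_arm: int      # nt downstream (acceptor side)
    gc: float
    kind: str = "shRNA"

    @property
    def guide(self) -> str:
        """The complementary (guide/probe) strand, 5'->3'."""
        return revcomp(self.sequence)


@dataclass(frozen=True)
class DesignResult:
    oligos: tuple[JunctionOligo, ...]
    rejected: dict[str, int] = field(default_factory=dict)


def design_junction_shrna(circle: CircleSeq, linear_mrnas: dict[str, str] | list[str],
                          length: int = 19, min_arm: int = 5,
                          gc_range: tuple[float, float] = (0.3, 0.6),
                          kind: str = "shRNA") -> DesignResult:
    """Junction-spanning knockdown oligos that cannot hit linear isoforms.

    Candidates are every ``length``-nt window covering the junction with both
    arms >= ``min_arm`` (there are length - 2*min_arm + 1 of them). Any
    candidate whose target site occurs as an exact substring of a provided
    linear mRNA is discarded — spanning the junction normally guarantees
    absence, but the check is enforced, not assumed. Survivors are filtered
    to ``gc_range`` and ranked: GC closest to 0.45, then the most symmetric
    arms, then A/T at the target 3' end (guide 5' end), then position.
    """
    if circle.length < length:
        raise ValueError("circle shorter than the oligo")
    if min_arm < 1 or 2 * min_arm > length:
        raise ValueError("min_arm must satisfy 1 <= min_arm <= length/2")
    mrnas = list(linear_mrnas.values()) if isinstance(linear_mrnas, dict) else list(linear_mrnas)
    mrnas = [normalize_nt(m) for m in mrnas]
    rejected = {"linear_match": 0, "gc_out_of_range": 0}
    candidates = []
    L = circle.length
    for start in range(L - length + min_arm, L - min_arm + 1):
        site = circle.window(start, length)
        left = L - start
        if any(site in m for m in mrnas):
            rejected["linear_match"] += 1
            continue
        gc = gc_fraction(site)
        if not (gc_range[0] <= gc <= gc_range[1]):
            rejected["gc_out_of_range"] += 1
            continue
        candidates.append(JunctionOligo(site, start, left, length - left, gc, kind))
    candidates.sort(key=lambda o: (abs(o.gc - 0.45), -min(o.left_arm, o.right_arm),
                                   0 if o.sequence[-1] in "AT" else 1, o.circ_offset))
    return DesignResult(tuple(candidates), rejected)


# ---------------------------------------------------------------------------
# divergent-primer specificity


@dataclass(frozen=True)
class PrimerReport:
    status: str                  # OK | NOT_FOUND
    circ_amplicon_len: int | None
    linear_amplicon: int | None  # None when the pair is circle-specific
    linear_hit: str | None = None


def check_divergent_primers(fwd: str, rev: str, circle: CircleSeq,
                            linear_mrnas: dict[str, str] | None = None) -> PrimerReport:
    """Amplicon arithmetic for a divergent RT-qPCR primer pair.

    On the circle a pair whose forward site lies downstream of the reverse
    site in the linear frame amplifies across the backsplice junction; the
    amplicon runs forward from the fwd site to the end of the rev site,
    wrapping the junction if needed. Binding is exact-match only. The report
    also says whether the same pair could amplify any provided linear mRNA
    (a specificity failure for a circle-specific assay).
    """
    fwd, rev = normalize_nt(fwd), normalize_nt(rev)
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be >= 15 nt")
    s2 = circle.sequence + circle.sequence
    L = circle.length
    rev_site = revcomp(rev)
    f = s2.find(fwd)
    r = s2.find(rev_site)
    if f < 0 or f >= L or r < 0 or r >= L or len(fwd) > L or len(rev) > L:
        return PrimerReport("NOT_FOUND", None, None)
    circ_len = (r + len(rev_site) - f - 1) % L + 1
    linear_len, hit = None, None
    for name, m in (linear_mrnas or {}).items():
        m = normalize_nt(m)
        f2 = m.find(fwd)
        if f2 < 0:
            continue
        r2 = m.find(rev_site, f2)
        if r2 >= 0:
            linear_len, hit = r2 + len(rev_site) - f2, name
            break
    return PrimerReport("OK", circ_len, linear_len, hit)


# ---------------------------------------------------------------------------
# circular ORFs


@dataclass(frozen=True)
class CircularOrf:
    start: int           # circle coordinate of the A of ATG
    aa_length: int
    spans_junction: bool
    laps: int
    peptide: str
    classification: str  # terminated | rolling


def find_circular_orfs(circle: CircleSeq, start_codon: str = "ATG",
                       max_laps: int = 3) -> list[CircularOrf]:
    """Every ORF opened by a start codon anywhere on the circle.

    Translation proceeds across the backsplice junction until a stop codon
    (terminated) or, failing that, until the reading frame re-enters its own
    start or the lap budget is exhausted (rolling; reported with
    laps = max_laps as the cap flag, peptide = one period of the repeat).
    ``spans_junction`` is true iff the ORF's covered arc, stop included,
    crosses the junction. Peptides exclude the stop.
    """
    seq = circle.sequence
    L = circle.length
    if L < 3:
        raise ValueError("circle shorter than one codon")
    orfs = []
    for p in range(L):
        if circle.window(p, 3) != start_codon:
            continue
        codons = []
        terminated = False
        t = 0
        while True:
            q = p + 3 * t
            if t > 0 and q % L == p:       # frame re-entered the start
                break
            if q + 3 > p + max_laps * L:   # lap budget exhausted
                break
            codon = circle.window(q, 3)
            if codon in STOP_CODONS:
                terminated = True
                break
            codons.append(codon)
            t += 1
        n_read = t + (1 if terminated else 0)
        end_linear = p + 3 * n_read
        peptide = str(Seq("".join(codons)).translate())
        orfs.append(CircularOrf(
            start=p,
            aa_length=len(peptide),
            spans_junction=end_linear > L if terminated else True,
            laps=(end_linear - 1) // L if terminated else max_laps,
            peptide=peptide,
            classification="terminated" if terminated else "rolling",
        ))
    orfs.sort(key=lambda o: (o.start, -o.aa_length))
    return orfs


def compare_n_terminus(circ_peptide: str, linear_protein: str) -> tuple[int, str]:
    """Longest shared N-terminal prefix and the circle-specific suffix.

    The suffix is the discriminating region a targeted-MS assay must cover.
    """
    if not circ_peptide or not linear_protein:
        raise ValueError("empty peptide")
    n = 0
    for a, b in zip(circ_peptide, linear_protein):
        if a != b:
            break
        n += 1
    return n, circ_peptide[n:]


# ---------------------------------------------------------------------------
# canonical miRNA seed sites


SITE_CLASS_ORDER = ("6mer", "7mer-A1", "7mer-m8", "8mer")


@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    site_class: str
    circle_position: int   # start of the full site on the linearization
    spans_junction: bool
    site_sequence: str


def scan_seed_sites(circle: CircleSeq, mirnas: dict[str, str],
                    min_class: str = "7mer-A1") -> list[SeedSite]:
    """Canonical seed-site scan (6mer/7mer-A1/7mer-m8/8mer) on the circle.

    The site core is the reverse complement of miRNA positions 2-7; m8
    pairing extends the core 5' on the target, the A1 anchor is an A
    immediately 3' of it. The scan wraps the junction so sites split across
    it are found exactly once; only the highest class at each core position
    is reported. No context scoring is attempted.
    """
    if min_class not in SITE_CLASS_ORDER:
        raise ValueError(f"unknown site class {min_class!r}")
    min_rank = SITE_CLASS_ORDER.index(min_class)
    L = circle.length
    seq = circle.sequence
    sites = []
    for mid, mseq in mirnas.items():
        m = normalize_nt(mseq)
        if len(m) < 8:
            raise ValueError(f"miRNA {mid} shorter than 8 nt")
        core = revcomp(m[1:7])      # pairs miRNA positions 2-7
        m8_base = revcomp(m[7])     # target base pairing miRNA position 8
        for p in range(L):
            if circle.window(p, 6) != core:
                continue
            has_m8 = seq[(p - 1) % L] == m8_base
            has_a1 = seq[(p + 6) % L] == "A"
            if has_m8 and has_a1:
                cls = "8mer"
            elif has_m8:
                cls = "7mer-m8"
            elif has_a1:
                cls = "7mer-A1"
            else:
                cls = "6mer"
            if SITE_CLASS_ORDER.index(cls) < min_rank:
                continue
            start = (p - 1) % L if has_m8 else p
            slen = 6 + (1 if has_m8 else 0) + (1 if has_a1 else 0)
            sites.append(SeedSite(mid, cls, start, start + slen > L,
                                  circle.window(start, slen)))
    sites.sort(key=lambda s: (s.mirna_id, s.circle_position))
    return sites
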