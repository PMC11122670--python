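"""Transcript-structure model of a circRNA-producing gene locus.

Coordinates are 0-based half-open on the + strand of the reference
throughout the package; GFF3 (1-based inclusive) is converted at the I/O
boundary. "Acceptor position" denotes the 5' boundary of an exon on the
transcribed strand: for a + strand exon that is its ``start``, for a -
strand exon its half-open ``end``. The intronic AG dinucleotide of a
(+ strand) acceptor occupies the two bases immediately before that
boundary. A transcript's first exon begins at a transcription start site
and therefore has no acceptor; splice-acceptor usage is evaluated on
internal exons only.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace

from .seqs import iupac_regex, revcomp

Interval = tuple[int, int]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TranscriptModel:
    """One splice variant: an ordered chain of exons on the gene strand.

    ``exons`` are genomic half-open intervals in transcription (5'->3')
    order: ascending for +, descending for - strand genes.
    """

    transcript_id: str
    exons: tuple[Interval, ...]
    coding: bool = False
    is_canonical: bool = False

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(
                    f"transcript {self.transcript_id}: bad exon interval ({s},{e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"({s1},{e1}) and ({s2},{e2})")

    @property
    def span(self) -> Interval:
        genomic = sorted(self.exons)
        return genomic[0][0], genomic[-1][1]


@dataclass(frozen=True)
class LocusModel:
    """A gene: transcripts sharing one reference sequence and strand."""

    gene_id: str
    strand: str
    sequence_ref: str
    transcripts: tuple[TranscriptModel, ...]
    canonical_id: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate transcript ids")
        if self.canonical_id not in ids:
            raise ValueError(f"canonical transcript {self.canonical_id} not in locus")

    @property
    def span(self) -> Interval:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return min(starts), max(ends)

    def transcript(self, tid: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == tid:
                return t
        raise KeyError(tid)

    @property
    def canonical(self) -> TranscriptModel:
        return self.transcript(self.canonical_id)


@dataclass(frozen=True)
class CircDef:
    """A backsplice event: donor joins the upstream acceptor, circularizing
    ``exon_chain`` (genomic intervals, transcription order)."""

    chrom: str
    strand: str
    acceptor_pos: int  # 5' boundary of the first chain exon (strand-aware)
    donor_pos: int     # 3' boundary of the last chain exon (strand-aware)
    exon_chain: tuple[Interval, ...]

    def __post_init__(self):
        if not self.exon_chain:
            raise ValueError("empty exon chain")
        first, last = self.exon_chain[0], self.exon_chain[-1]
        acc = first[0] if self.strand == "+" else first[1]
        don = last[1] if self.strand == "+" else last[0]
        if acc != self.acceptor_pos or don != self.donor_pos:
            raise ValueError("acceptor/donor do not match the exon chain boundaries")

    @property
    def span(self) -> Interval:
        genomic = sorted(self.exon_chain)
        return genomic[0][0], genomic[-1][1]


VERDICTS = ("SA_MUTABLE", "SA_SHARED", "SD_MUTABLE", "NEITHER")


@dataclass(frozen=True)
class UsageRow:
    transcript_id: str
    uses_sa: bool
    uses_sd: bool
    overlap_class: str  # exonic | intronic | none


@dataclass(frozen=True)
class SpliceUsageReport:
    rows: tuple[UsageRow, ...]
    verdict: str
    protected: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class CrypticScanResult:
    found: bool
    cryptic_acceptor_pos: int | None  # strand-aware boundary, genomic frame
    lost_prefix_len: int | None
    shifted_circ: "CircDef | None" = None

    NO_CRYPTIC = "NO_CRYPTIC"

    @property
    def status(self) -> str:
        return "OK" if self.found else self.NO_CRYPTIC


@dataclass(frozen=True)
class RflpResult:
    allele_fragments: dict[str, tuple[int, ...]]
    het_fragments: tuple[int, ...]
    discriminates: bool


# ---------------------------------------------------------------------------
# strand-aware boundary helpers


def exon_acceptor(exon: Interval, strand: str) -> int:
    return exon[0] if strand == "+" else exon[1]


def exon_donor(exon: Interval, strand: str) -> int:
    return exon[1] if strand == "+" else exon[0]


def internal_acceptors(tx: TranscriptModel, strand: str) -> set[int]:
    return {exon_acceptor(e, strand) for e in tx.exons[1:]}


def internal_donors(tx: TranscriptModel, strand: str) -> set[int]:
    return {exon_donor(e, strand) for e in tx.exons[:-1]}


# ---------------------------------------------------------------------------
# operations


def classify_overlap(tx: TranscriptModel, circ: CircDef, strand: str | None = None) -> str:
    """Relationship between a transcript and the circularized exon block.

    exonic: a chain exon intersects a transcript exon; intronic: the chain
    lies within the transcript's genomic span without exon overlap (shared
    only as intron); none: outside the span. Antisense comparisons are out
    of scope and rejected.
    """
    if strand is not None and strand != circ.strand:
        raise ValueError("strand mismatch: antisense relationships are out of scope")
    for cs, ce in circ.exon_chain:
        for ts, te in tx.exons:
            if cs < te and ts < ce:
                return "exonic"
    ts, te = tx.span
    cs, ce = circ.span
    if ts <= cs and ce <= te:
        return "intronic"
    return "none"


def splice_site_usage(locus: LocusModel, circ: CircDef,
                      protected: set[str] | None = None) -> SpliceUsageReport:
    """Which transcripts use the backsplice SA/SD, and the knockout verdict.

    A transcript uses the SA iff the circ acceptor is the acceptor boundary
    of one of its internal exons (first exons start at a TSS and have no
    acceptor); SD analogously on internal donors. The verdict is computed
    against ``protected`` (default: all coding transcripts): if none of them
    uses the SA the site can be mutated to ablate the circle specifically.
    """
    if locus.strand != circ.strand:
        raise ValueError("strand mismatch between locus and circRNA definition")
    if protected is None:
        protected = {t.transcript_id for t in locus.transcripts if t.coding}
    rows = []
    for tx in locus.transcripts:
        rows.append(UsageRow(
            transcript_id=tx.transcript_id,
            uses_sa=circ.acceptor_pos in internal_acceptors(tx, locus.strand),
            uses_sd=circ.donor_pos in internal_donors(tx, locus.strand),
            overlap_class=classify_overlap(tx, circ),
        ))
    sa_shared = any(r.uses_sa for r in rows if r.transcript_id in protected)
    sd_shared = any(r.uses_sd for r in rows if r.transcript_id in protected)
    any_sa = any(r.uses_sa for r in rows)
    any_sd = any(r.uses_sd for r in rows)
    if not sa_shared:
        verdict = "SA_MUTABLE"
    elif not sd_shared:
        verdict = "SD_MUTABLE"
    elif any_sa or any_sd:
        verdict = "SA_SHARED"
    else:  # degenerate: circ boundaries coincide with no splice site at all
        verdict = "NEITHER"
    return SpliceUsageReport(rows=tuple(rows), verdict=verdict,
                             protected=frozenset(protected))


def apply_mutations(sequence: str, edits: list[tuple[int, str, str]]) -> str:
    """Apply (position, ref, alt) edits; positions refer to the input frame.

    Edits are validated against the reference and applied right-to-left so
    earlier positions stay meaningful even if an edit changes length.
    """
    spans = []
    for pos, ref, alt in edits:
        if pos < 0 or pos + len(ref) > len(sequence):
            raise ValueError(f"edit at {pos} outside sequence")
        if sequence[pos:pos + len(ref)] != ref:
            raise ValueError(
                f"reference mismatch at position {pos}: expected {ref!r}, "
                f"found {sequence[pos:pos + len(ref)]!r}")
        spans.append((pos, pos + len(ref)))
    spans.sort()
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping edits at positions {s1} and {s2}")
    out = sequence
    for pos, ref, alt in sorted(edits, key=lambda e: e[0], reverse=True):
        out = out[:pos] + alt + out[pos + len(ref):]
    return out


def cryptic_acceptor_scan(sequence: str, original_acceptor_pos: int,
                          window: int = 100, strand: str = "+",
                          circ: CircDef | None = None) -> CrypticScanResult:
    """First AG strictly downstream of a destroyed canonical acceptor.

    ``sequence`` is the (already mutated) reference; ``original_acceptor_pos``
    the strand-aware boundary of the lost acceptor. The scan walks at most
    ``window`` nt downstream on the transcribed strand; the cryptic acceptor
    boundary sits immediately 3' of the found AG, and ``lost_prefix_len`` is
    how much of the original first circularized exon the shifted backsplice
    would drop. No AG in the window is a NO_CRYPTIC result, not an error.
    """
    if strand == "-":
        mirrored = cryptic_acceptor_scan(revcomp(sequence),
                                         len(sequence) - original_acceptor_pos,
                                         window=window, strand="+")
        if not mirrored.found:
            return CrypticScanResult(False, None, None)
        pos = len(sequence) - mirrored.cryptic_acceptor_pos
        res = CrypticScanResult(True, pos, mirrored.lost_prefix_len)
    else:
        a = original_acceptor_pos
        if a >= 2 and sequence[a - 2:a] == "AG":
            raise ValueError("canonical AG still intact at the acceptor; "
                             "apply the disrupting edit first")
        res = CrypticScanResult(False, None, None)
        for q in range(max(a - 1, 0), min(a - 1 + window, len(sequence) - 1)):
            if sequence[q:q + 2] == "AG":
                res = CrypticScanResult(True, q + 2, q + 2 - a)
                break
        if not res.found:
            return res
    if circ is not None and res.found:
        return replace(res, shifted_circ=shift_circ_acceptor(circ, res.cryptic_acceptor_pos))
    return res


def shift_circ_acceptor(circ: CircDef, new_acceptor_pos: int) -> CircDef:
    """CircDef with its first exon trimmed to a downstream cryptic acceptor."""
    first = circ.exon_chain[0]
    if circ.strand == "+":
        if not (first[0] < new_acceptor_pos < first[1]):
            raise ValueError("cryptic acceptor outside the first circ exon")
        new_first = (new_acceptor_pos, first[1])
    else:
        if not (first[0] < new_acceptor_pos < first[1]):
            raise ValueError("cryptic acceptor outside the first circ exon")
        new_first = (first[0], new_acceptor_pos)
    return CircDef(circ.chrom, circ.strand, new_acceptor_pos, circ.donor_pos,
                   (new_first,) + circ.exon_chain[1:])


def digest_fragments(amplicon: str, motif: str = "CTNAG", cut_offset: int = 1) -> tuple[int, ...]:
    """Fragment lengths from cutting at every motif occurrence (forward strand)."""
    if not amplicon:
        raise ValueError("empty amplicon")
    if not (0 <= cut_offset <= len(motif)):
        raise ValueError("cut offset outside motif")
    pat = iupac_regex(motif)
    cuts = sorted({m.start() + cut_offset for m in pat.finditer(amplicon)
                   if m.start() + len(motif) <= len(amplicon)})
    cuts = [c for c in cuts if 0 < c < len(amplicon)]
    bounds = [0] + cuts + [len(amplicon)]
    return tuple(b - a for a, b in zip(bounds, bounds[1:]))


def rflp_digest(amplicon: str, motif: str = "CTNAG", cut_offset: int = 1,
                alt_amplicon: str | None = None) -> RflpResult:
    """RFLP genotyping prediction for one amplicon, optionally two alleles.

    The heterozygote is the multiset union of the two alleles' fragments;
    ``discriminates`` says whether the allele fragment multisets differ at
    all (i.e. whether the digest can genotype the edit).
    """
    wt = digest_fragments(amplicon, motif, cut_offset)
    alleles = {"WT": tuple(sorted(wt, reverse=True))}
    if alt_amplicon is None:
        return RflpResult(alleles, alleles["WT"], False)
    alt = digest_fragments(alt_amplicon, motif, cut_offset)
    alleles["ALT"] = tuple(sorted(alt, reverse=True))
    # gel bands of a heterozygote: every size present in either allele
    het = tuple(sorted(set(wt) | set(alt), reverse=True))
    return RflpResult(alleles, het, Counter(wt) != Counter(alt))
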