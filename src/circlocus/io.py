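"""Readers and writers for the standard formats at the package boundary.

GFF3 is 1-based inclusive on disk and converted losslessly to the internal
0-based half-open frame; BED is native half-open. FASTA goes through
Biopython, GFF3 parsing through gffutils.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .locus import CircDef, LocusModel, TranscriptModel


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path, wrap: int = 60) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# GFF3


def _attrs(**kv) -> str:
    return ";".join(f"{k}={v}" for k, v in kv.items() if v is not None)


def write_gff3(locus: LocusModel, path: str | Path, source: str = "circlocus") -> None:
    """Gene/mRNA/exon/CDS features, 1-based inclusive coordinates.

    Coding transcripts get CDS features mirroring their exons (no UTR
    modelling); the canonical transcript carries a ``canonical=1`` attribute.
    """
    chrom, strand = locus.sequence_ref, locus.strand
    lines = ["##gff-version 3"]

    def feat(ftype, start, end, attrs):
        return "\t".join([chrom, source, ftype, str(start + 1), str(end), ".",
                          strand, ".", attrs])

    gs, ge = locus.span
    lines.append(feat("gene", gs, ge, _attrs(ID=locus.gene_id)))
    for tx in locus.transcripts:
        ts, te = tx.span
        lines.append(feat("mRNA", ts, te, _attrs(
            ID=tx.transcript_id, Parent=locus.gene_id,
            biotype="protein_coding" if tx.coding else "processed_transcript",
            canonical="1" if tx.is_canonical else None)))
        for i, (es, ee) in enumerate(sorted(tx.exons)):
            lines.append(feat("exon", es, ee, _attrs(
                ID=f"{tx.transcript_id}.exon{i + 1}", Parent=tx.transcript_id)))
            if tx.coding:
                lines.append(feat("CDS", es, ee, _attrs(
                    ID=f"{tx.transcript_id}.cds{i + 1}", Parent=tx.transcript_id)))
    Path(path).write_text("\n".join(lines) + "\n")


def _pick_canonical(transcripts: list[TranscriptModel]) -> str:
    """Fallback when the annotation carries no canonical tag: longest CDS,
    then longest transcript, then lexicographic id."""
    def cds_len(t):
        return sum(e - s for s, e in t.exons) if t.coding else 0

    def tx_len(t):
        return sum(e - s for s, e in t.exons)

    return sorted(transcripts, key=lambda t: (-cds_len(t), -tx_len(t),
                                              t.transcript_id))[0].transcript_id


def parse_annotation(gff3_path: str | Path, fasta_path: str | Path,
                     gene_id: str | None = None) -> LocusModel:
    """Parse a GFF3 + FASTA pair into the internal locus model.

    Coordinates are converted to 0-based half-open; exon bounds are
    validated against the sequence. With several genes in the file,
    ``gene_id`` selects one (required in that case).
    """
    sequences = read_fasta(fasta_path)
    try:
        db = gffutils.create_db(str(gff3_path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="error")
    except Exception as exc:  # gffutils reports the offending line itself
        raise ValueError(f"malformed GFF3 {gff3_path}: {exc}") from exc
    genes = list(db.features_of_type("gene"))
    if not genes:
        raise ValueError("no gene feature in GFF3")
    if gene_id is not None:
        genes = [g for g in genes if g.id == gene_id]
        if not genes:
            raise ValueError(f"gene {gene_id!r} not found")
    elif len(genes) > 1:
        raise ValueError("multiple genes in GFF3; pass gene_id")
    gene = genes[0]
    if gene.seqid not in sequences:
        raise ValueError(f"GFF3 references sequence {gene.seqid!r} absent from FASTA")
    seqlen = len(sequences[gene.seqid])
    strand = gene.strand
    transcripts = []
    canonical = None
    for tx in db.children(gene, level=1):
        exons = []
        coding = False
        for child in db.children(tx, level=1):
            if child.featuretype == "exon":
                s, e = child.start - 1, child.end
                if not (0 <= s < e <= seqlen):
                    raise ValueError(
                        f"exon {s}-{e} of {tx.id} outside sequence bounds (0-{seqlen})")
                exons.append((s, e))
            elif child.featuretype == "CDS":
                coding = True
        exons.sort(reverse=(strand == "-"))
        is_canon = tx.attributes.get("canonical", ["0"])[0] == "1" \
            or "Ensembl_canonical" in tx.attributes.get("tag", [])
        transcripts.append(TranscriptModel(tx.id, tuple(exons), coding, is_canon))
        if is_canon:
            canonical = tx.id
    if canonical is None:
        canonical = _pick_canonical(transcripts)
        transcripts = [
            TranscriptModel(t.transcript_id, t.exons, t.coding,
                            t.transcript_id == canonical) for t in transcripts]
    return LocusModel(gene.id, strand, gene.seqid, tuple(transcripts), canonical)


# ---------------------------------------------------------------------------
# BED


def write_circ_bed(circ: CircDef, path: str | Path, name: str | None = None) -> None:
    """BED6 record of the backsplice span; the name carries the exon chain."""
    s, e = circ.span
    chain = ",".join(f"{a}-{b}" for a, b in circ.exon_chain)
    name = name or f"circ|{chain}"
    Path(path).write_text(
        "\t".join([circ.chrom, str(s), str(e), name, "0", circ.strand]) + "\n")


def read_circ_bed(path: str | Path) -> CircDef:
    line = next(l for l in Path(path).read_text().splitlines()
                if l.strip() and not l.startswith("#"))
    fields = line.split("\t")
    if len(fields) < 6:
        raise ValueError(f"circ BED needs 6 columns, got {len(fields)}")
    chrom, _, _, name, _, strand = fields[:6]
    try:
        chain = tuple(tuple(map(int, part.split("-")))
                      for part in name.split("|")[-1].split(","))
    except ValueError:
        raise ValueError(f"cannot parse exon chain from BED name {name!r}") from None
    if strand == "-":
        chain = tuple(sorted(chain, reverse=True))
        acc, don = chain[0][1], chain[-1][0]
    else:
        chain = tuple(sorted(chain))
        acc, don = chain[0][0], chain[-1][1]
    return CircDef(chrom, strand, acc, don, chain)


def write_bed6(intervals: list[tuple[int, int, str]], chrom: str, strand: str,
               path: str | Path) -> None:
    lines = ["\t".join([chrom, str(s), str(e), name, "0", strand])
             for s, e, name in intervals]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed6(path: str | Path) -> list[tuple[int, int, str]]:
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        if len(f) < 4:
            raise ValueError(f"{path}:{ln}: BED line has <4 columns")
        out.append((int(f[1]), int(f[2]), f[3]))
    return out


# ---------------------------------------------------------------------------
# TSV with provenance header


def write_tsv(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    """TSV with '#' header comments recording the producing parameter set."""
    with open(path, "w") as fh:
        for k, v in (params or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
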