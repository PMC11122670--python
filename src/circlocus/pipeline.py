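"""End-to-end "characterize this circRNA locus" pipeline.

Stage order follows the analysis workflow: locus model -> RCM mapping ->
knockout feasibility (splice-acceptor usage, acceptor mutation, cryptic-SA
prediction) -> circle construction (junction oligos, primers, ORFs, seed
sites) -> discriminative peptides / PRM targets -> qPCR quantification.
Outputs are one TSV per stage plus a machine-readable summary; runs are
deterministic for a fixed config.
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .circle import (build_circle, check_divergent_primers, design_junction_shrna,
                     compare_n_terminus, find_circular_orfs, scan_seed_sites)
from .locus import apply_mutations, cryptic_acceptor_scan, splice_site_usage
from .peptides import DigestParams, discriminative_peptides, prm_inclusion_list
from .quant import circ_linear_ratio, relative_expression
from .rcm import RcmParams, annotate_repeats, find_rcm, rank_candidates
from .seqs import revcomp

SUMMARY_SCHEMA = "circlocus-summary/1"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_STAGES = ("rcm", "ko", "circle", "orfs", "seeds", "peptides", "quant")


@dataclass
class PipelineConfig:
    fasta: str
    gff3: str
    circ_bed: str
    outdir: str
    repeat_bed: str | None = None
    mirna_fasta: str | None = None
    ct_tsv: str | None = None
    seed: int = 0
    gene_id: str | None = None
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    rcm: RcmParams = field(default_factory=RcmParams)
    digest: DigestParams = field(default_factory=lambda: DigestParams(
        max_missed_cleavages=1, min_length=6))
    shrna: dict = field(default_factory=lambda: {"length": 19, "min_arm": 5,
                                                 "gc_range": (0.3, 0.6)})
    primers: tuple[str, str] | None = None
    protected: list[str] | None = None
    quant_cfg: dict = field(default_factory=lambda: {
        "circ_target": "circ", "linear_target": "linear",
        "housekeepers": ("HK1", "HK2"), "reference_condition": "WT"})
    cryptic_window: int = 100
    top_rcm: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(raw)
        for sub, typ in (("rcm", RcmParams), ("digest", DigestParams)):
            if isinstance(kw.get(sub), dict):
                allowed = {f.name for f in dataclasses.fields(typ)}
                bad = set(kw[sub]) - allowed
                if bad:
                    raise ValueError(f"unknown {sub} parameter(s): {sorted(bad)}")
                kw[sub] = typ(**kw[sub])
        if isinstance(kw.get("stages"), dict):
            bad = set(kw["stages"]) - set(_STAGES)
            if bad:
                raise ValueError(f"unknown stage(s): {sorted(bad)}")
            stages = {s: True for s in _STAGES}
            stages.update(kw["stages"])
            kw["stages"] = stages
        if kw.get("primers") is not None:
            kw["primers"] = tuple(kw["primers"])
        if base is not None:
            for key in ("fasta", "gff3", "circ_bed", "repeat_bed", "mirna_fasta",
                        "ct_tsv", "outdir"):
                if kw.get(key):
                    kw[key] = str((base / kw[key]).resolve()
                                  if not Path(kw[key]).is_absolute() else kw[key])
        return cls(**kw)

    def validate(self) -> None:
        for key in ("fasta", "gff3", "circ_bed"):
            p = getattr(self, key)
            if not p or not Path(p).exists():
                raise ValueError(f"required input {key!r} missing: {p}")
        for key in ("repeat_bed", "mirna_fasta", "ct_tsv"):
            p = getattr(self, key)
            if p and not Path(p).exists():
                raise ValueError(f"configured input {key!r} does not exist: {p}")


def merged_exon_intervals(locus) -> list[tuple[int, int]]:
    ivs = sorted(e for t in locus.transcripts for e in t.exons)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def flanking_introns(locus, circ, seq_len: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Genomic intervals intronic in every isoform, adjacent to the circle.

    "Upstream" is 5' of the backsplice acceptor on the transcribed strand.
    Computed from the union of all transcript exons, so an alternative exon
    covering the acceptor shrinks the upstream intron accordingly. The -
    strand case is solved by mirroring onto the + logic.
    """
    merged = merged_exon_intervals(locus)
    acc, don = circ.acceptor_pos, circ.donor_pos
    if locus.strand == "-":
        mirrored = [(seq_len - e, seq_len - s) for s, e in reversed(merged)]
        up, down = _flanking_plus(mirrored, seq_len - acc, seq_len - don, seq_len)
        return ((seq_len - up[1], seq_len - up[0]),
                (seq_len - down[1], seq_len - down[0]))
    return _flanking_plus(merged, acc, don, seq_len)


def _flanking_plus(merged, acc, don, seq_len):
    # upstream gap ends where the exon block containing (or starting at) the
    # acceptor begins; downstream gap starts where the donor's block ends
    covering = [s for s, e in merged if s < acc < e]
    gap_end = covering[0] if covering else acc
    prev_ends = [e for s, e in merged if e <= gap_end]
    up = (max(prev_ends, default=0), gap_end)
    covering = [e for s, e in merged if s < don < e]
    gap_start = covering[-1] if covering else don
    next_starts = [s for s, e in merged if s >= gap_start]
    down = (gap_start, min(next_starts, default=seq_len))
    if up[0] >= up[1] or down[0] >= down[1]:
        raise ValueError("could not locate flanking introns around the circle")
    return up, down


def translate_first_orf(mrna: str) -> str:
    """Translation from the first ATG of a linear mRNA (ribosome-scanning
    rule), to the first stop or the 3' end."""
    from Bio.Seq import Seq
    i = mrna.find("ATG")
    if i < 0:
        return ""
    n = (len(mrna) - i) // 3 * 3
    return str(Seq(mrna[i:i + n]).translate(to_stop=True))


def _log(msg: str, stage: str) -> None:
    print(f"[circlocus:{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the summary.

    A stage failure aborts the run with the stage name and cause; outputs of
    completed stages are retained next to a ``FAILED.<stage>`` marker file.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema": SUMMARY_SCHEMA, "seed": config.seed}
    on = config.stages

    def run_stage(name, fn):
        if not on.get(name, True):
            return
        _log("running", name)
        try:
            fn()
        except Exception as exc:
            (outdir / f"FAILED.{name}").write_text(str(exc) + "\n")
            raise PipelineError(name, exc) from exc

    if not any(on.values()):
        (outdir / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=True))
        return summary

    sequences = cio.read_fasta(config.fasta)
    locus = cio.parse_annotation(config.gff3, config.fasta, gene_id=config.gene_id)
    circ = cio.read_circ_bed(config.circ_bed)
    genome = sequences[locus.sequence_ref]
    state: dict = {}

    def stage_rcm():
        up_iv, down_iv = flanking_introns(locus, circ, len(genome))
        def iseq(iv):
            s = genome[iv[0]:iv[1]]
            return s if locus.strand == "+" else revcomp(s)
        hits = find_rcm(iseq(up_iv), iseq(down_iv), config.rcm)
        if config.repeat_bed:
            reps = cio.read_bed6(config.repeat_bed)
            def local(iv, intron):
                s, e, = iv
                if locus.strand == "+":
                    return s - intron[0], e - intron[0]
                return intron[1] - e, intron[1] - s
            up_reps = [(*local((s, e), up_iv), n) for s, e, n in reps
                       if s < up_iv[1] and up_iv[0] < e]
            down_reps = [(*local((s, e), down_iv), n) for s, e, n in reps
                         if s < down_iv[1] and down_iv[0] < e]
            hits = annotate_repeats(hits, up_reps, down_reps)
        ranked = rank_candidates(hits, config.top_rcm)
        df = pd.DataFrame([{
            "up_start": h.up_start, "up_end": h.up_end,
            "down_start": h.down_start, "down_end": h.down_end,
            "length": h.length, "identity": round(h.identity, 4),
            "score": h.score, "gaps": h.n_gaps,
            "repeats": ",".join(h.repeat_overlap)} for h in hits])
        cio.write_tsv(df, outdir / "rcm.tsv", dataclasses.asdict(config.rcm))
        from .rcm import alignment_text
        (outdir / "rcm_alignments.txt").write_text(
            "\n".join(alignment_text(h, iseq(up_iv), iseq(down_iv)) for h in hits)
            + "\n" if hits else "")
        state["rcm_hits"] = hits
        summary["rcm"] = {
            "n_hits": len(hits),
            "top_candidates": [{"length": h.length, "identity": round(h.identity, 4),
                                "score": h.score,
                                "up": list(h.up_interval), "down": list(h.down_interval)}
                               for h in ranked]}

    def stage_ko():
        report = splice_site_usage(locus, circ,
                                   set(config.protected) if config.protected else None)
        df = pd.DataFrame([dataclasses.asdict(r) for r in report.rows])
        cio.write_tsv(df, outdir / "splice_usage.tsv", {"verdict": report.verdict})
        acc = circ.acceptor_pos
        if locus.strand == "+":
            edit = (acc - 2, genome[acc - 2:acc], "TC")
        else:
            edit = (acc, genome[acc:acc + 2], revcomp("TC"))
        mutated = apply_mutations(genome, [edit])
        scan = cryptic_acceptor_scan(mutated, acc, window=config.cryptic_window,
                                     strand=locus.strand, circ=circ)
        cio.write_tsv(pd.DataFrame([{
            "status": scan.status,
            "cryptic_acceptor_pos": scan.cryptic_acceptor_pos,
            "lost_prefix_len": scan.lost_prefix_len}]),
            outdir / "cryptic_sa.tsv", {"window": config.cryptic_window})
        state["mutated_genome"] = mutated
        state["cryptic"] = scan
        summary["ko"] = {"verdict": report.verdict,
                         "sa_users": [r.transcript_id for r in report.rows if r.uses_sa],
                         "cryptic_sa": {"status": scan.status,
                                        "lost_prefix_len": scan.lost_prefix_len}}

    def mrnas():
        return {t.transcript_id:
                "".join((genome[s:e] if locus.strand == "+" else revcomp(genome[s:e]))
                        for s, e in t.exons)
                for t in locus.transcripts}

    def stage_circle():
        circle = build_circle(genome, circ)
        state["circle"] = circle
        linear = mrnas()
        design = design_junction_shrna(circle, linear, **config.shrna)
        df = pd.DataFrame([dataclasses.asdict(o) for o in design.oligos])
        cio.write_tsv(df, outdir / "junction_oligos.tsv",
                      {**config.shrna, "rejected": design.rejected})
        summary["circle"] = {"length": circle.length,
                             "n_oligos": len(design.oligos),
                             "oligos": [o.sequence for o in design.oligos[:5]],
                             "rejected": design.rejected}
        if config.primers:
            rep = check_divergent_primers(*config.primers, circle, linear)
            summary["circle"]["primers"] = dataclasses.asdict(rep)

    def stage_orfs():
        circle = state.get("circle") or build_circle(genome, circ)
        orfs = find_circular_orfs(circle)
        df = pd.DataFrame([dataclasses.asdict(o) for o in orfs])
        cio.write_tsv(df, outdir / "circular_orfs.tsv", {})
        spanning = [o for o in orfs
                    if o.classification == "terminated" and o.spans_junction]
        best = max(spanning, key=lambda o: o.aa_length, default=None)
        state["circ_orf"] = best
        summary["orfs"] = {"n_orfs": len(orfs), "n_junction_spanning": len(spanning),
                           "best": None if best is None else {
                               "start": best.start, "aa_length": best.aa_length,
                               "peptide": best.peptide}}

    def stage_seeds():
        if not config.mirna_fasta:
            return
        circle = state.get("circle") or build_circle(genome, circ)
        sites = scan_seed_sites(circle, cio.read_fasta(config.mirna_fasta))
        df = pd.DataFrame([dataclasses.asdict(s) for s in sites])
        cio.write_tsv(df, outdir / "seed_sites.tsv", {})
        summary["seeds"] = {"n_sites": len(sites),
                            "n_mirnas": len({s.mirna_id for s in sites})}

    def stage_peptides():
        circle = state.get("circle") or build_circle(genome, circ)
        spanning = [o for o in find_circular_orfs(circle)
                    if o.classification == "terminated" and o.spans_junction]
        proteome = {tid: translate_first_orf(seq)
                    for tid, seq in mrnas().items()
                    if locus.transcript(tid).coding}
        proteome = {k: v for k, v in proteome.items() if v}
        # the circle-encoded product of interest is the ORF sharing the
        # canonical protein's N terminus (it reuses the gene's start codon
        # and diverges only past the backsplice junction), not merely the
        # longest chance ORF on the circle
        canon = proteome.get(locus.canonical_id, "")
        best = max(spanning,
                   key=lambda o: ((compare_n_terminus(o.peptide, canon)[0]
                                   if canon else 0), o.aa_length),
                   default=None)
        if best is None:
            summary["peptides"] = {"n_prm_targets": 0, "note": "no junction-spanning ORF"}
            return
        disc = discriminative_peptides(best.peptide, proteome, config.digest)
        ions = prm_inclusion_list([t.sequence for t in disc])
        df = pd.DataFrame([{"peptide": ion.sequence, "charge": ion.charge,
                            "neutral_mass": round(ion.neutral_mass, 5), "mz": ion.mz}
                           for ion in ions])
        cio.write_tsv(df, outdir / "prm_targets.tsv",
                      dataclasses.asdict(config.digest))
        shared = {tid: compare_n_terminus(best.peptide, prot)[0]
                  for tid, prot in proteome.items()}
        summary["peptides"] = {
            "circ_orf_aa": best.aa_length,
            "max_shared_prefix_aa": max(shared.values(), default=0),
            "n_prm_targets": len(ions),
            "inclusion_list": [{"peptide": i.sequence, "charge": i.charge, "mz": i.mz}
                               for i in ions]}

    def stage_quant():
        if not config.ct_tsv:
            return
        table = cio.read_tsv(config.ct_tsv)
        q = config.quant_cfg
        hks = tuple(q["housekeepers"])
        circ_e = relative_expression(table, q["circ_target"], hks,
                                     q.get("reference_condition"))
        lin_e = relative_expression(table, q["linear_target"], hks,
                                    q.get("reference_condition"))
        ratio = circ_linear_ratio(table, q["circ_target"], q["linear_target"], hks)
        cio.write_tsv(pd.concat([circ_e, lin_e]), outdir / "expression.tsv", q)
        cio.write_tsv(ratio, outdir / "circ_linear_ratio.tsv", q)
        by_cond = (circ_e.groupby("condition")["value"].mean().to_dict()
                   if "condition" in circ_e.columns else
                   {"all": float(circ_e["value"].mean())})
        summary["quant"] = {"circ_mean_by_condition":
                            {k: round(float(v), 4) for k, v in by_cond.items()}}

    run_stage("rcm", stage_rcm)
    run_stage("ko", stage_ko)
    run_stage("circle", stage_circle)
    run_stage("orfs", stage_orfs)
    run_stage("seeds", stage_seeds)
    run_stage("peptides", stage_peptides)
    run_stage("quant", stage_quant)

    (outdir / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=True))
    return summary
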