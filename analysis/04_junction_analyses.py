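#!/usr/bin/env python
"""Backsplice-junction analyses on the assembled circle.

Builds the circular sequence, designs junction-spanning shRNA target sites
that cannot hit any linear isoform, checks the divergent RT-qPCR primer
pair for circle specificity, finds circular ORFs (including the engineered
junction-spanning 95-aa product and its shared N terminus with the linear
protein), and scans for canonical miRNA seed sites across the junction.
Writes results/junction_oligos.tsv, circular_orfs.tsv and seed_sites.tsv.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from circlocus.circle import (build_circle, check_divergent_primers,
                              compare_n_terminus, design_junction_shrna,
                              find_circular_orfs, scan_seed_sites)
from circlocus.io import write_tsv
from circlocus.pipeline import translate_first_orf
from circlocus.synthetic import tulp4_mimic_bundle


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    mimic = tulp4_mimic_bundle(args.seed)
    b = mimic.bundle
    circle = build_circle(b.genome_sequence, b.circ)
    mrnas = b.linear_mrnas()
    print(f"circle: {circle.length} nt")

    design = design_junction_shrna(circle, mrnas)
    write_tsv(pd.DataFrame([dataclasses.asdict(o) for o in design.oligos]),
              args.outdir / "junction_oligos.tsv", design.rejected)
    print(f"shRNA candidates spanning the junction: {len(design.oligos)} "
          f"(rejected: {design.rejected}); top: "
          f"{design.oligos[0].sequence if design.oligos else '-'}")

    rep = check_divergent_primers(*mimic.primers, circle, mrnas)
    print(f"divergent primers: {rep.status}, circular amplicon "
          f"{rep.circ_amplicon_len} bp, linear amplicon {rep.linear_amplicon}")

    orfs = find_circular_orfs(circle)
    write_tsv(pd.DataFrame([dataclasses.asdict(o) for o in orfs]),
              args.outdir / "circular_orfs.tsv", {})
    linear = translate_first_orf(mrnas[b.gene.canonical_id])
    spanning = [o for o in orfs
                if o.classification == "terminated" and o.spans_junction]
    best = max(spanning, key=lambda o: (compare_n_terminus(o.peptide, linear)[0],
                                        o.aa_length))
    shared, suffix = compare_n_terminus(best.peptide, linear)
    print(f"junction-spanning ORF: {best.aa_length} aa from circle position "
          f"{best.start}; shares aa 1-{shared} with the linear protein, "
          f"circle-specific tail {suffix!r}")

    sites = scan_seed_sites(circle, b.mirnas)
    write_tsv(pd.DataFrame([dataclasses.asdict(s) for s in sites]),
              args.outdir / "seed_sites.tsv", {"min_class": "7mer-A1"})
    for s in sites:
        print(f"seed site: {s.mirna_id} {s.site_class} at {s.circle_position} "
              f"(spans junction: {s.spans_junction})")


if __name__ == "__main__":
    main()
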