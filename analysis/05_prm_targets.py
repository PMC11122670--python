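#!/usr/bin/env python
"""Discriminative tryptic peptides and PRM inclusion masses.

Digests the circle-specific 95-aa product (trypsin, <=1 missed cleavage,
peptides >=6 aa) and removes every peptide also produced by the linear
proteome; the survivors cover the circle-specific C terminus. For each, the
monoisotopic [M+nH]n+ is computed at the predicted ESI charge (K/R count
+ 1), unmodified, giving the targeted-MS inclusion list. Writes
results/prm_targets.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from circlocus.circle import build_circle, compare_n_terminus, find_circular_orfs
from circlocus.io import write_tsv
from circlocus.peptides import DigestParams, discriminative_peptides, prm_inclusion_list
from circlocus.pipeline import translate_first_orf
from circlocus.synthetic import tulp4_mimic_bundle


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    b = tulp4_mimic_bundle(args.seed).bundle
    circle = build_circle(b.genome_sequence, b.circ)
    proteome = {tid: translate_first_orf(seq)
                for tid, seq in b.linear_mrnas().items()
                if b.gene.transcript(tid).coding}
    proteome = {k: v for k, v in proteome.items() if v}
    canon = proteome[b.gene.canonical_id]
    spanning = [o for o in find_circular_orfs(circle)
                if o.classification == "terminated" and o.spans_junction]
    orf = max(spanning, key=lambda o: (compare_n_terminus(o.peptide, canon)[0],
                                       o.aa_length))

    params = DigestParams(max_missed_cleavages=1, min_length=6)
    disc = discriminative_peptides(orf.peptide, proteome, params)
    ions = prm_inclusion_list([p.sequence for p in disc])
    df = pd.DataFrame([{"peptide": i.sequence, "charge": i.charge,
                        "neutral_mass": round(i.neutral_mass, 5), "mz": i.mz}
                       for i in ions])
    write_tsv(df, args.outdir / "prm_targets.tsv",
              {"max_missed_cleavages": 1, "min_length": 6, "modifications": "none"})
    print(f"{len(disc)} discriminative peptides from the {orf.aa_length}-aa "
          f"circle-specific product:")
    for i in ions:
        print(f"  {i.sequence}\t[M+{i.charge}H]{i.charge}+ = {i.mz:.5f}")


if __name__ == "__main__":
    main()
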