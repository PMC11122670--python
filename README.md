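# circlocus

Computational characterisation of a circRNA-producing gene locus, built for
the kind of study where one exonic circle (a backsplice joining the donor of
a downstream exon to the acceptor of an upstream one) must be mapped,
specifically knocked out, detected, and tested for coding potential — all
before touching a pipette.

The toolkit covers six linked analyses:

1. **RCM mapping** — reverse complementary matches between the two introns
   flanking the circularized exon block. Base pairing between such inverted
   repeats (often SINE copies) promotes backsplicing. `rcm.find_rcm` is a
   seed-and-extend local aligner run between the upstream intron and the
   reverse complement of the downstream one: exact *w*-mer seeds, X-drop
   ungapped extension, affine-gap X-drop extension, redundancy resolution,
   and ranking by length and percent complementarity.
2. **Knockout feasibility** — `locus.splice_site_usage` decides whether the
   backsplice acceptor (SA) is dispensable: if no protected (coding)
   transcript uses it as an internal-exon acceptor, an AG→TC edit ablates
   the circle without touching the linear isoforms (verdict `SA_MUTABLE`).
3. **Cryptic acceptor prediction** — after the AG→TC edit,
   `locus.cryptic_acceptor_scan` finds the next downstream 5′-AG-3′ that can
   substitute, and reports how much of the circle the shifted backsplice
   would lose. `locus.rflp_digest` predicts restriction-fragment genotyping
   (e.g. Dde I, CTNAG cut C^TNAG) for the edited allele.
4. **Junction-centric design** — the backsplice junction is the only
   circle-specific sequence. `circle.design_junction_shrna` enumerates
   junction-spanning knockdown oligos and *proves* selectivity by substring
   search against every linear mRNA; `circle.check_divergent_primers` does
   the amplicon arithmetic for outward-facing RT-qPCR primers on circular
   topology.
5. **Circular ORFs and PRM targets** — `circle.find_circular_orfs`
   translates across the junction (handling multi-lap and stop-less
   "rolling" reads); `peptides.discriminative_peptides` digests the
   circle-specific product with trypsin and keeps peptides absent from the
   linear proteome; `peptides.mz` computes exact monoisotopic [M+nH]n+
   values for a parallel-reaction-monitoring inclusion list.
6. **qPCR quantification** — `quant.relative_expression` implements
   2^(−ΔCt) normalization against the mean of two housekeepers with
   rescaling to a reference condition, plus circle/linear ratio reporting.

Everything runs on fully synthetic loci produced by `circlocus.synthetic`,
which plants each structure (inverted repeats of exact identity, a cryptic
AG, a junction-spanning ORF sharing its N terminus with the linear protein,
a junction miRNA site, two-condition Ct tables) so that every analysis has
a known ground truth.

## Worked example

```bash
python analysis/01_build_locus.py    # write the synthetic locus fixture
python analysis/02_map_rcms.py      # RCMs in the flanking introns
python analysis/03_knockout_design.py
python analysis/04_junction_analyses.py
python analysis/05_prm_targets.py
python analysis/06_qpcr_quant.py
```

Output of the knockout and PRM steps on the default locus (seed 0):

```
verdict: SA_MUTABLE (SA used only by ['TX-202', 'TX-203'])
cryptic SA: OK, shifted circle loses 11 of 310 nt
RFLP: WT (646,) bp, edited (446, 200) bp, discriminates=True

4 discriminative peptides from the 95-aa circle-specific product:
  NLRGHNSESCK   [M+3H]3+ = 415.53153
  GHNSESCK      [M+2H]2+ = 431.17961
  GHNSESCKSPSR  [M+3H]3+ = 430.19481
  SPSRTFQS      [M+2H]2+ = 455.22487
```

Reading: only two non-coding minor transcripts use the circle's splice
acceptor, so mutating its AG is predicted to ablate the circle specifically
(`SA_MUTABLE`); if a cryptic AG 9 nt into the exon takes over, the circle
shrinks by 11 nt; the edit creates one Dde I site splitting the 646-bp
genotyping amplicon into 446 + 200 bp. The circle encodes a 95-aa product
identical to the linear protein over aa 1–84 and divergent past the
junction; its tryptic peptides that cannot come from any linear protein,
with their exact precursor m/z values at the predicted charge, form the
inclusion list for targeted MS.

The same computations are scriptable through the CLI
(`circlocus run|ko-feasibility|cryptic-sa|rflp|rcm-scan|build-circle|design-shrna|orfs|seed-scan|check-primers|digest|prm-targets|qpcr-norm|make-fixture`),
with the umbrella `circlocus run config.yaml` executing all stages and
writing one TSV per stage plus a machine-readable `summary.yaml`.

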