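# Methods

This note records the models, conventions and numerical choices behind each
module, what the synthetic data do and do not emulate, and the design
decisions taken where more than one convention was defensible.

## Coordinate frame and splice-site conventions

All internal coordinates are 0-based half-open on the + strand of the
reference; GFF3 (1-based inclusive) is converted at the I/O boundary and
BED is native. A single frame avoids off-by-one drift between modules.

The *acceptor position* of an exon is the boundary at its first transcribed
base — `start` for a + strand exon, the half-open `end` for a − strand
exon. The intronic AG dinucleotide sits in the two bases 5′ of that
boundary on the transcribed strand. The *donor position* is the symmetric
3′ boundary. A transcript's first exon begins at a transcription start
site, not a splice acceptor, so splice-acceptor usage is evaluated over
internal exons only; donors over all but the last exon. A backsplice
definition (`CircDef`) stores the acceptor/donor boundaries plus the
circularized exon chain in transcription order.

Minus-strand loci are handled by strand-aware boundary logic, not by
re-coding the algorithms: the generator's `mirror_bundle` produces a
reverse-complemented twin of any locus, and the test suite checks that
usage reports, cryptic-acceptor scans and circle sequences are identical on
both strands.

## Splice-acceptor dispensability

A transcript *uses* the backsplice SA iff the circ acceptor boundary equals
one of its internal-exon acceptor boundaries (likewise SD on donors). The
knockout verdict is computed against a protected set (default: all coding
transcripts):

- `SA_MUTABLE` — no protected transcript uses the SA; an AG→TC edit is
  predicted to ablate only the circle.
- `SD_MUTABLE` — the SA is shared but the SD is circle-specific.
- `SA_SHARED` — both backsplice boundaries are used by protected
  transcripts; no site-level knockout is circle-specific.
- `NEITHER` — reserved for the degenerate case in which neither boundary
  coincides with any transcript splice site (not produced on well-formed
  input).

Transcript overlap with the circle is classified `exonic` (any chain exon
intersects a transcript exon), `intronic` (chain within the transcript
span, shared only as intron) or `none`. Antisense comparisons are rejected.

## Cryptic acceptor scan

After the canonical AG is destroyed, the scan returns the first 5′-AG-3′
strictly downstream of the mutated site within a window (default 100 nt,
configurable; how far downstream a cryptic AG remains usable is an
empirical question the module does not attempt to answer, and no usage
efficiency is predicted). The shifted backsplice starts immediately 3′ of
the found AG; `lost_prefix_len` is the number of original circle bases
dropped. Absence of an AG is a `NO_CRYPTIC` result, not an error. The scan
refuses to run if the canonical AG is still intact, which catches
called-before-edit mistakes.

## RFLP genotyping

Fragments come from cutting at every IUPAC-motif occurrence on the forward
strand (overlapping occurrences included; default Dde I, CTNAG cut after
the C). Heterozygotes are reported as the union of the two alleles' band
sizes without intensity modelling; `discriminates` compares the allele
fragment multisets. Fragment lengths always sum to the amplicon length, a
property fuzzed in the tests.

## RCM search

`find_rcm` aligns the upstream intron against the reverse complement of
the downstream intron and reports hits in each intron's own frame.

- **Seeding.** Exact `word_size` matches; words containing N never seed,
  and N scores as a mismatch during extension.
- **Extension.** X-drop ungapped extension around each seed (ties in the
  running maximum prefer the longer extension, keeping mirrored searches
  symmetric), followed by affine-gap X-drop extension from both ends when
  the ungapped score reaches `gap_trigger`. The gapped extension is an
  antidiagonal dynamic program with three affine states and full traceback;
  a cell budget bounds pathological inputs.
- **Semantics.** Every seed is extended independently, so each hit is the
  best-scoring segment *containing* that seed; results are deduplicated and
  a redundancy filter drops hits sharing more than `overlap_frac` (default
  0.5) of either interval with a higher-scoring hit. The only extension
  shortcut is skipping seeds inside a previously found perfect-identity
  segment, where re-extension provably reproduces the same interval.
- **Scores.** Default parameters mimic blastn (+2/−3, gap −5/−2, word 11,
  X-drop 20, min score 30, min length 20). No E-value statistics are
  computed: candidates are ranked by length, then identity, then score,
  matching the length-and-percent-complementarity criterion the analysis
  is built around. Each hit carries its alignment ops string, so the score
  is exactly recomputable from the reported intervals — an invariant the
  tests enforce.
- **Sensitive profile.** `RcmParams.sensitive()` (word 5, +1/−3,
  min score 20) exists for short diverged repeats: at 85% identity with
  evenly spaced mismatches, exact runs are only 5–6 nt, so word 11 cannot
  seed; and +1/−3 scoring keeps alignment endpoints inside ≥75%-identity
  sequence, so reported identities track the repeat rather than lucky
  flanking matches. This profile is what the recovery analyses use.
- **Scope.** Cross-intron mode only by default; repeat annotation attaches
  any interval overlapping a hit by ≥1 nt (interval-tree lookup, checked
  against an all-pairs oracle). No same-intron self-RCMs unless asked, no
  translated search, no secondary-structure energetics.

## Circle topology

The circle is linearized from the acceptor-side first base, so the
backsplice junction — the only circle-specific sequence — is the 0/length
boundary. All analyses are rotation-invariant up to the corresponding
coordinate shift (tested).

- **Junction oligos.** A length-19 window (configurable) must cover the
  junction with both arms ≥5 nt; there are exactly `length − 2·min_arm + 1`
  such frames. Selectivity is guaranteed, not assumed: any candidate whose
  target site occurs verbatim in a linear mRNA is discarded, and a reason
  histogram is returned when nothing survives. Ranking (GC closest to
  0.45, most symmetric arms, A/T at the guide 5′ end) is explicit
  configuration, since no community standard exists for junction oligos.
- **Primers.** Exact-match binding only; melting temperature and mismatch
  tolerance are out of scope. A forward site downstream of the reverse site
  in the linear frame implies a junction-crossing product whose length is
  computed modulo the circle.
- **Circular ORFs.** Every start codon on the circle opens an ORF;
  translation crosses the junction until a stop (terminated) or until the
  frame re-enters its own start or exhausts `max_laps` (rolling — reported
  with the lap cap and one period of the repeating peptide, never silently
  dropped). `spans_junction` is true iff the covered arc, stop included,
  crosses the junction. Terminated ORFs with ≤2 laps are verified against a
  linear translation of the tripled sequence. When one product must be
  singled out (pipeline, PRM stage), the junction-spanning ORF sharing the
  longest N-terminal prefix with the canonical protein is chosen — the
  biologically meaningful product reuses the gene's start codon and
  diverges only past the junction — rather than the longest chance ORF.
- **Seed sites.** Canonical classes only (6mer, 7mer-A1, 7mer-m8, 8mer,
  defined on the reverse complement of miRNA positions 2–8 plus the A1
  anchor); the scan wraps the junction so split sites are found exactly
  once, the highest class per core position wins, and no context scoring or
  free-energy term is attempted.

## Peptides and PRM masses

Trypsin cleaves C-terminal to K/R, suppressed before proline (on by
default); missed cleavages are enumerated up to a cap, and the protein C
terminus is a valid peptide C terminus, which is what allows a C-terminal
peptide without K/R. I and L are distinct residues of equal mass.

Masses use the standard monoisotopic residue table with water 18.010565 Da
and proton 1.007276 Da; the test suite cross-checks against pyteomics.
Named modifications cover carbamidomethyl-Cys (+57.021464) and Met
oxidation (+15.994915), but inclusion lists for synthetic peptides are
computed **unmodified** — the use case is standards ordered as bare
peptides, so fixed database-search modifications are deliberately not
applied unless requested. The predicted precursor charge is one proton per
K/R plus the N-terminal amine, clipped to charges whose m/z falls inside
the MS1 scan range (default 350–1500).

Discriminative peptides are the tryptic peptides of the circle-specific
product absent from the tryptic digests (same parameters) of every linear
protein. Linear proteins are obtained from coding transcripts by the
ribosome-scanning rule (translation from the first ATG of the mRNA).

## qPCR quantification

ΔCt subtracts the arithmetic mean of two housekeeper Ct values (the
geometric mean of their linear abundances — the specific mean used is
recorded in output metadata); expression is 2^(−ΔCt) with efficiency fixed
at 2.0, rescaled so the reference-condition mean is exactly 1. Technical
replicates are averaged on the Ct scale before ΔCt. Adding a constant to
every Ct of a sample leaves values unchanged (tested). The circle/linear
ratio flags a condition as `circ_predominant` when its mean ratio exceeds
1. No significance testing is performed here.

The planted-fold-change recovery checks use the mean absolute error of the
log2 estimate over many simulated tables against a 3·noise_sd/√n bound;
the estimator is unbiased, so the averaged error sits far inside the bound
while a single simulated experiment can land outside it, as any single
animal cohort would.

## Synthetic data: what it emulates, and what it does not

`make_locus` draws everything from one numpy PCG64 stream seeded by
`spec.seed`; outputs are byte-stable across runs. Introns are canonical
(GT…AG). Planted RCMs place a segment in the upstream intron and its
reverse complement in the downstream one with mismatches at evenly spaced
positions, so the planted identity is exact and reproducible; overlapping
plants and plants that would disturb the intron termini are rejected. The
acceptor exon is built AG-free up to the planted cryptic AG. SINE-like
annotations are interval labels around the plants — no repeat-family
sequence realism is attempted, and intron base composition is plain
GC-weighted random sequence.

The default locus mimics the studied gene's architecture: seven exons,
exons 2–3 circularized (310-nt circle), 2-kb flanking introns, six splice
variants — the canonical one starting at an alternative TSS 60 nt upstream
of the circ acceptor (so it shares the circle sequence exonically *without*
using the backsplice SA, which is internal to its first exon), two
non-coding minor variants splicing into the SA, and two transcripts holding
the circle only as intron (overlap classes exonic ×4 / intronic ×2).

`tulp4_mimic_bundle` additionally engineers the coding layout: a 95-aa ORF
starts 58 nt into the circle, reads 84 codons to the junction (those 84 aa
are shared with the linear protein, whose mRNA continues into exon 4 — its
first codon is pinned so divergence falls exactly at aa 85) and terminates
11 aa past it; the circle-specific tail ends in …NLRGHNSESCK + SPSRTFQS,
so trypsin with one missed cleavage yields the three discriminative
reporter peptides. The last 60 nt of the upstream intron are kept ATG-free
so the canonical mRNA's first ATG is the engineered one. Ct tables default
to the study condition of a 65.4% circle knockdown with unchanged linear
levels over two housekeepers.

Because all of this is planted, passing tests demonstrate that each method
recovers known structure under controlled noise — not that the methods are
calibrated for genomic repeat landscapes, real splice-site strength, or
instrument-grade MS behaviour. No read data, expression counts or spectra
are simulated.

## Problem sizes

The recovery analyses use 20 bundles × 4 plants (50–250 nt, identity
0.86–1.0) in 2-kb introns; oracle equivalence uses 200 random circles
(30–300 nt), 40 seed-scan circles, 10 short intron pairs for the exhaustive
diagonal oracle and 50 random proteins for digestion; oligo specificity is
fuzzed over 100 loci; quantification recovery over 50 simulated tables plus
20 replicate knockdown cohorts of 12 samples per genotype. These sizes keep
the whole analysis in the seconds range while leaving each statistical
check many standard deviations of margin.

## Known limitations

- The RCM search has no significance model; score thresholds are absolute.
- Splice-site usage is annotation-driven; it cannot flag an SA that is
  silent in the annotation but used in vivo, and branch points and
  polypyrimidine tracts are not modelled.
- Cryptic-acceptor prediction is positional only (first downstream AG);
  real usage efficiency depends on context the module does not score.
- Oligo design has no thermodynamics; primer binding is exact-match.
- The charge predictor is a counting heuristic, adequate for tryptic
  peptides in an inclusion-list workflow.
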