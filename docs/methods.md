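# Methods

## Profiles, coordinates and normalization

Input is a segmented absolute copy-number profile per sample: 1-based
inclusive coordinates, integer total copy number, diploid baseline 2.
Non-integer calls from upstream callers are rounded half-up, since the
component scheme is anchored on integer values and oscillation detection
requires integer states. Exactly 23 chromosomes are tallied (1–22 and X,
encoded 1–23 in `BoChr`); Y, M and unplaced contigs are dropped at read
time. chrX is treated autosome-like with baseline 2 (configurable via the
`baseline` argument of the feature and score functions).

Normalization sorts segments and merges adjacent same-chromosome runs of
equal copy number, including across coverage gaps. The merge guarantees
that every junction between retained segments is a true copy-number
breakpoint, which makes the breakpoint-derived features (`BP10MB`,
`BPArm`, `CNCP`) unambiguous; the cost is that a merged segment can span a
gap, so summed segment length is preserved only for gapless input.
Exome-derived segment tables are gapped; gaps do not themselves create
breakpoints, and a junction is counted between consecutive retained
segments regardless of gap size.

## Feature definitions and their edge cases

- **BP10MB** — windows of 10 Mb tiled from base 1 over each chromosome
  present in the profile, last partial window included; a junction is
  located at the end coordinate of its left segment. One observation per
  window (zeros included).
- **BPArm** — two observations (p, q) for every chromosome of the build,
  including chromosomes absent from the profile (count 0), so the
  observation count is invariant across samples of a cohort.
- **CN**, **SS** — one observation per segment (copy number; log10 length).
- **CNCP** — |Δcn| per junction.
- **OsCN** — per chromosome with ≥ 3 segments, walk positions i = 3..n
  with a counter that increments while cn_i = cn_{i−2} ≠ cn_{i−1}. The
  counter is emitted and reset when the condition breaks *while a chain is
  open*, and emitted unconditionally at the chromosome end. Thus
  [2,3,2,3,2] → [3] and [2,3,4] → [0]; chromosomes with < 3 segments emit
  nothing. Emitting the trailing counter (possibly 0) keeps quiet
  chromosomes represented in the OsCN distribution.
- **NC50** — smallest k such that the k chromosomes with most altered
  segments hold ≥ half of all altered segments; 0 for a fully diploid
  profile. Altered segments are counted, not altered megabases, keeping
  the feature event-count-based like the rest of the scheme.
- **BoChr** — chromosome index of each altered segment.

"Altered" everywhere means cn ≠ baseline (default 2).

## The 80-component scheme

Component bins are shipped as a package data file
(`data/cn_components_80.tsv`: feature, label, lower, upper, kind) so
alternative binnings can be dropped in without code change. The default:
BP10MB [0..5, >5] (7); BPArm [0..9, >9] (11); CN [0..8, >8] (10); CNCP
[0..5, >5] (7); OsCN [0..3, >3] (5); SS (log10 bp) bins at
2, 3, 4, 5, 5.5, 6, 6.5, 7, 7.5, 8, 8.5, 9 (13); NC50 [≤1, 2, 3, >3] (4);
BoChr [1..23] (23) — 80 in total, each feature's bins mutually exclusive
and exhaustive over feasible values (property-tested). Discrete bins match
a value exactly; range bins are half-open (lower, upper]. SBS catalogs use
the 96 pyrimidine-referenced trinucleotide classes in COSMIC lexicographic
order, with purine-reference records reverse-complemented before
classification.

## NMF, rank survey and exposures

The catalog is factorized by multiplicative updates under generalized KL
divergence (the classic scheme of the SBS-signature lineage): random
uniform initialization, up to 10,000 iterations, stop when the relative
objective change over 10 iterations falls below 1e-6, divisors and the
reconstruction clipped at 1e-9 to avoid division by zero. The objective is
non-increasing per update (asserted in tests) and the implementation is
cross-checked against scikit-learn's mu/KL solver. Restarts are seeded
from one `SeedSequence`, so results are bit-reproducible for a given seed.

The consensus matrix averages, over restarts, the indicator that two
samples load most on the same signature. The cophenetic coefficient is the
Pearson correlation between consensus dissimilarity (1 − consensus) and
the cophenetic distances of its average-linkage dendrogram; a degenerate
(constant) dissimilarity is defined as coefficient 1. The suggested rank —
largest k whose coefficient exceeds the next surveyed rank's by a margin
(default 0.01) — is advisory; rank choice also weighs interpretability,
which cannot be automated.

Signature columns are scaled to unit sum with the scale folded into the
exposure rows (leaving W·H unchanged, asserted to 1e-12); absolute
exposures therefore sum to a sample's reconstructed event count, and
relative exposures are row shares. Copy-number signatures are ordered by
ascending weighted-median SS bin (shortest-segment signatures first,
mirroring ranking by median segment length), with weighted-mean bin and
column index as deterministic tie-breaks; catalogs without an SS feature
fall back to descending total exposure.

## Fitting, bootstrap, detection

Single-sample fitting solves the nonnegative least-squares program
min ‖Wx − v‖², x ≥ 0 (`scipy.optimize.nnls`); it is checked against an
exhaustive simplex grid search at step 0.01 on 3-signature problems. No
stochastic refinement (e.g. annealing) is layered on top: the program is
convex and NNLS returns its global optimum, so a refinement pass could
only reproduce it.
Bootstrap catalogs are multinomial draws of size n = Σv at probabilities
v/n — resampling preserves the sample's total event count because catalogs
are counts and the observed component probabilities are what the bootstrap
conditions on. The presence p-value is the one-sided fraction of bootstrap
relative exposures ≤ the exposure cutoff (default 0.01). A signature is
detected cohort-wide when strictly more than `min_tumors` (default 10)
tumors have bootstrap p-value < 0.05. The detection-probability curve
computes per-tumor bootstrap support once and then subsamples tumors
without replacement per repetition; this isolates the cohort-size effect
the curve measures and makes large repetition counts cheap.

## Scores

TD = amplified segment (cn > baseline) with 1 kb ≤ length ≤ 2 Mb.
TDP = TD_total / (Σ_chr |TD_obs − TD_exp| + 1) × L, with TD_exp
apportioned by chromosome length share (the conventional expectation
model of the tandem-duplicator-phenotype literature) and L the total TD
size in Mb; the score is 0 when no TDs exist. The grouping — dispersion
penalty in the denominator, size factor outside — is the natural reading
of the defining formula. Chromothripsis state score = Σ_chr (count of
consecutive (2,1,2) triples)²; overlapping triples each count, and strict
adjacency is required (no gap tolerance). Both scores are checked against
brute-force oracles on random profiles.

## Association testing

Continuous/ordinal covariates: Pearson correlation, two-sided. Binary:
Mann-Whitney U, two-sided, exact distribution when combined n ≤ 20 without
ties, normal approximation with tie correction otherwise; the effect is
the difference of group means. Benjamini–Hochberg FDR is applied across
the full signature × covariate grid of one call; rows with < 3 usable
pairs or an empty group are reported NA and excluded from the adjustment.

## Simulator

The simulator provides planted ground truth, not realism. Five processes:
focal amplification (Poisson(weight × 120) insertions of 10–100 kb at
cn ≥ 9), tandem duplication (Poisson(weight × 120) insertions of
100 kb–2 Mb at cn 3), WGD (Bernoulli(weight) baseline shift 2 → 4),
chromothripsis (Poisson(weight × 5) rewrites of a chromosome region into
20–60 segments alternating cn 2/1) and quiet (nothing). Weights per sample
are Dirichlet(1); placement is uniform with overlap rejection (bounded
retries, events skipped on failure). These defaults give median segment
counts of roughly 150 per sample on hg38 and mean pairwise cosine ≈ 0.64
between the pure-process mean catalogs — separable enough that
factorization at the planted rank recovers the processes (mean best-match
cosine ≈ 0.96 on the default 200-sample cohort). Ground truth records the
per-sample weights and each process's expected catalog (mean over 20
pure-process samples).

Not emulated: allele-specific copy number, purity/ploidy estimation error,
caller-specific segmentation artifacts, inter-chromosomal structure of real
chromothripsis, and correlated event placement. Passing recovery tests
therefore shows the pipeline is correct and identifiable under its own
generative assumptions, not that five processes explain any particular
tumor cohort.

## Problem sizes and numerical defaults

Worked examples and oracle tests use the 2-chromosome toy build (chr1
30 Mb / boundary 15 Mb, chr2 20 Mb / boundary 10 Mb). Cohort-level checks
use the default simulated cohort (200 samples, 5 processes, seed 1) with
30 NMF restarts for extraction and the k = 5 vs 6 cophenetic comparison;
bootstrap checks use 500–1000 draws. Extraction n_runs defaults to 50 in
the API and CLI.

## Known limitations

- The component bin boundaries beyond the integer-anchored ones are this
  package's defaults; alternative published binnings can be supplied as a
  scheme TSV.
- NMF non-uniqueness: with strongly overlapping processes (e.g. WGD vs
  quiet backgrounds, cosine ≈ 0.99 between their pure catalogs) individual
  factors can mix; stability across restarts, not uniqueness, is what the
  cophenetic survey certifies.
- The chromothripsis score is a simplified state estimate based only on
  (2,1,2) oscillation; it is not a structural-variant-based caller.
- Reconciliation of discordant Sequenza/FACETS calls is out of scope; one
  caller's table is taken as input.
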