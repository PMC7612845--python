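# Methods

This note documents the models and procedures implemented in `emh`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data tests do and do not demonstrate.

## Normalization and scoring

Raw counts are library-size normalized to counts-per-10,000 and
log-transformed: `value(g,c) = log(1 + count(g,c) * 1e4 / library(c))`.
This is the de-facto droplet scRNA-seq convention; the scale is
configurable. Cells with zero total counts stay all-zero and are warned
about rather than dropped (QC is out of scope; inputs are assumed
pre-filtered).

Signature ("module") scores follow the standard bin-matched
control-subtraction scheme: genes are ranked by dataset-wide mean
expression and cut into `n_bins` equal-size bins (default 25); for each
signature gene, `n_ctrl` control genes (default 50) are sampled without
replacement from its bin, excluding all signature genes; the score is the
mean expression of the signature genes minus the mean of the pooled
controls. Excluding signature genes from the control pool makes the
constant-expression case exact (score = v − w) and avoids
self-cancellation for small bins. Control sampling is seeded per
(gene-set content, top-level seed) so identical gene lists score
identically wherever they appear — this is what makes the
swap-the-halves symmetry of the identity ratio exact.

Two caveats follow from the binning and matter for interpretation:

- Scores are only comparable **within one scoring cohort**. The bins are
  cohort-wide; scoring two samples separately and comparing the numbers
  mixes two different control baselines.
- A program elevated in *every* cell of the cohort is partially absorbed
  by the bin matching (the program genes are matched against other
  high-mean genes). Mixed cohorts — the intended use — do not have this
  problem.

Cell-cycle phases use the usual two-score rule: a cell with both S and
G2M scores negative is G1; otherwise the larger score wins, with ties
going to S (arbitrary but fixed). Thresholding noisy scores at zero
over-calls cycling for cells with weak programs; the composition module's
cross-tissue comparisons are therefore most meaningful on differences
between tissues, not absolute fractions. The shipped
`data/cell_cycle_synthetic.gmt` lists the *simulator's* S/G2M program
genes for demo pipelines; real data needs a published cell-cycle list
supplied as GMT.

## Composition statistics

Cluster/group fractions are computed per (donor, tissue); donor-level
fractions, not pooled cells, are the unit for cross-tissue ratio
comparisons. Early/late progenitor ratios are ratios of summed group
fractions, with a flagged infinity for empty denominators.

Cycling between tissues is compared with a two-sided exact binomial test
of the comparison tissue's S-G2-M count against the reference tissue's
pooled fraction `p0 = x_ref / n_ref` ("minlike" two-sidedness: sum the
probabilities of all outcomes no more likely than the observed one). The
test conditions on `p0` as a fixed null. That is appropriate when the
reference is large (pooled clusters of a whole tissue); with a small
reference the unaccounted sampling noise in `p0` makes the test
anticonservative (measured ~0.08 type-I at n_ref = 400 vs 0.048 at
n_ref = 2000 for n = 120 comparisons). An unconditional two-sample test
(Boschloo/Fisher) is deliberately out of scope.

## Lower-bound branch expansion

Along an ordered branch with stage abundances `N_s` and S-G2-M fractions
`f_s`, active cells are `A_s = N_s * f_s`. Assuming every division is a
symmetric differentiating division (both daughters advance), the
amplification per transition and its division count are

    a_s = max(1, N_{s+1} / max(A_s, 1)),   d_s = log2(a_s),   D = Σ d_s.

The floors encode the lower-bound reading: at least one active cell is
assumed present, and shrinking stages contribute zero (not negative)
divisions. `D` depends only on abundance *ratios*, so relative cluster
abundances suffice — consistent with using scRNA-seq cluster sizes. The
formula is isolated in `estimate_expansion` so alternatives (influx,
death terms) could be swapped in; such terms are out of scope. "Active"
defaults to transcriptionally assigned S-G2-M but cycling fractions can
be supplied externally (e.g. Ki-67-based); the source is a labelled field
on `BranchModel`.

On the deterministic doubling fixture (1000/2000/4000/8000 cells, half
active) the estimator returns exactly 6 total divisions (amplification 4
per transition) and on the 1000/4000 fixture exactly 3. Multinomial
sampling of 50,000 cells from the doubling branch recovers D = 6 with
mean absolute error ~0.035 (per-seed sd ~0.044, so single seeds can err
slightly above 0.1).

## Medullary/extramedullary identity

Two reference HSC/MPP poles are compared gene-by-gene with a two-sided
Wilcoxon rank-sum test (exact null for tie-free groups of ≤ 20 cells,
tie-corrected normal approximation otherwise), fold change
`log2((mean expm1 A + 1)/(mean expm1 B + 1))`, Benjamini-Hochberg FDR.
Genes passing FDR < 0.05 and |LFC| > 0.2 are ranked by |LFC| and the top
50 per direction form the paired identity signature (medullary = pole A
by convention; the CLI forces explicit pole naming).

Each cell is scored for both halves; scores are converted to fractional
ranks over the scored cohort (rank/n ∈ (0,1]) and their ratio
`R = rank_med / rank_extramed` is the per-cell identity ratio. Rank
normalization is the central reconstruction choice here: raw module
scores can be negative and scale-dependent, whereas fractional ranks are
strictly positive, scale-free, and make R = 1 mean exactly "equal
standing of the two scores within the cohort", giving the
classification threshold at 1 its meaning. A min-shifted raw-score ratio
is available behind `method="raw"`. Because ranks are relative to the
cohort, per-sample summaries (`identity_by_sample`) score **all samples
in one shared cohort** and then summarize each sample by its median R
with a seeded bootstrap 95% CI; within a single homogeneous sample the
ratio is ~1 by construction and carries no information. Samples are
called medullary (median R > 1, CI excluding 1), extramedullary
(mirrored), or indeterminate (CI spans 1, or fewer than 20 cells).

## Pre-ranked GSEA

The classical weighted running-sum statistic: descending metric order,
hits add `|metric|^p` normalized by the summed hit weights (p = 1
default, p = 0 available), misses subtract `1/(N − N_hits)`; ES is the
signed maximum deviation. The null is gene-label permutation — the only
null available in the pre-ranked setting — computed once per set size and
shared (the null distribution depends only on the size). The permutation
p-value is two-sided on |ES|: `p = (1 + #{|ES_null| ≥ |ES|})/(n_perm+1)`,
which is exactly calibrated under the null and floors at
`1/(n_perm+1)`. NES divides ES by the mean |null ES| of matching sign;
FDR is the standard pooled-NES ratio estimate, clipped to [0, 1]. For
two-group inputs the default ranking metric is
`sign(log2FC) * −log10(p)` from the Wilcoxon DE table.

## Limiting-dilution analysis

Single-hit Poisson model: `P(response | dose d) = 1 − exp(−f·d)`. The
MLE of the per-cell frequency `f` is found by direct 1-D optimization of
the binomial log-likelihood in `β = log f` — the intercept of the
equivalent complementary-log-log GLM with log-dose offset. Confidence
intervals are Wald on β (numerical observed information) by default,
switching to profile likelihood when any dose group is saturated.
All-negative tables return f = 0 with the exact one-sided upper bound
`−ln(α)/Σ n_i d_i`; all-positive tables return only a lower bound;
both are marked `boundary` and excluded from ratio tests. "1 in N"
reporting rounds N up (conservative). Frequency ratios between two
experiments are tested by a likelihood-ratio test against a shared-f
null (χ², 1 df). Over 1,000 simulated replicates at f = 0.001 with doses
500/1000/2000 and 200 animals each, the median estimate is within 10% of
truth and the 95% CI covers it in ≥ 93% of replicates.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume,
not real transcriptomes:

- **Counts**: negative binomial (gamma-Poisson) with shared
  inverse-dispersion θ (default 2; variance = μ + μ²/θ). Zero inflation,
  batch effects, ambient RNA and doublets are not modelled — NB suffices
  for the rank- and score-based statistics downstream.
- **Baseline**: per-gene lognormal(0, 1) means drawn from a dedicated
  `baseline_seed` (fixed default), *separate* from the sampling seed.
  The baseline represents gene-specific expression propensities — a
  property of the biology being emulated, shared across samples — so
  independently simulated datasets are score-comparable. Setting
  distinct baseline seeds deliberately introduces dataset-level batch
  offsets.
- **Structure**: tissues draw cluster labels multinomially from their
  composition; clusters carry multiplicative fold-effect programs;
  each cell cycles with its cluster's probability, cycling cells split
  S/G2M 50/50 (downstream analyses only use the combined S-G2-M
  fraction), and S/G2M cells get phase-program fold effects. Per-cell
  library sizes are lognormal (default median 2,500 counts, sigma 0.3,
  a typical post-QC droplet depth).
- All randomness flows from the single config seed through one
  generator; identical configs are bit-identical.

Default effect sizes for identity benchmarks: 50 program genes per pole
at fold 2, 2,000 genes, 400 training cells per pole, 500-cell test
samples. Under these conditions a medullary-program cell outscores an
extramedullary-program cell on the medullary signature with probability
≈ 0.99 (shared-cohort scoring), the planted programs are recovered at
≥ 80% by the DE + top-gene selection, and held-out samples are
classified correctly in ≥ 95% of seed replicates. Passing these tests
shows the pipeline is statistically sound under its own generative
assumptions; it does not certify performance on real data with batch
effects, nested donor structure, or programs that violate the
multiplicative NB model.

## Problem sizes and numerical choices

Test and demo problem sizes (hundreds of cells, 500–2,000 genes,
100–1,000 permutation/bootstrap replicates) were chosen so the whole
suite runs in well under a minute while keeping Monte-Carlo standard
errors small enough for the stated bounds; statistical checks state
their tolerances as multiples of the exact binomial/multinomial SE.
Tie-breaks and degenerate cases are fixed and documented at the point of
implementation: phase ties go to S; empty stages and zero active-cell
transitions are floored and flagged rather than erroring; zero-library
cells normalize to zero with a warning; composition ratios with empty
denominators return flagged infinities.
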