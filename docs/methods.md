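# Methods

## The generative model

The simulator emulates a targeted bisulfite PCR sequencing (Bis-PCR-Seq)
ageing study. A panel of `n_regions` amplicons (default 12, each 300 bp, on
its own scaffold) carries `total_cpgs` CpG dinucleotides in total (default
51), distributed as evenly as possible and placed at least 2 bp apart.
Background sequence is random but scan-and-repaired so that *every* CG
dinucleotide in the references is a tracked site; a substring scan of the
emitted FASTA is therefore an exact oracle for the CpG count.

Each CpG `j` has a baseline methylation fraction `m0_j` and a drift slope
`s_j` in fraction/week; a tissue `t` multiplies all slopes by a rate `r_t`
(liver ≡ 1). Sample `i` of age `a_i` has true methylation

    p_ij = clamp(m0_j + s_j · r_t(i) · a_i + ε_ij, 0, 1),  ε_ij ~ N(0, σ_b²).

`DriftModel.plant` marks `n_admp` sites (default 23 of 51) as age-drifting
with slope magnitudes uniform on [3e-4, 6e-4]/week and random sign; baselines
are drawn low (0.05–0.25) for gaining sites and high (0.75–0.95) for losing
sites so the drift rarely saturates over a 39–1,196-week lifespan, and
uniform on (0.1, 0.9) for null sites. Default noise and sequencing
parameters are typical Bis-PCR-Seq values: σ_b = 0.03, bisulfite conversion
efficiency 0.99, per-base substitution error 0.001, and 200 reads per
amplicon — comfortably above the 50× coverage cut-off. Cohort ages are drawn
uniformly over the stated range (39–1,144 weeks for the training livers,
43–1,196 for the second batch and skin), which maximizes regression leverage;
the skin rate multiplier defaults to 0.6.

Reads are simulated single-end spanning the full amplicon, so every read
covers every CpG of its region — pairing and read length are sequencing
details that do not affect counting in an amplicon design. Only the
original-top bisulfite strand is emitted. Per read, each CpG cytosine is
methylated with probability `p_ij`; unmethylated cytosines (CpG or not)
convert C→T with the conversion efficiency; sequencing error then substitutes
each base uniformly among the other three. The simulator returns its own
per-(sample, site) ledger of methylated draws, which is the exact expected
output of a perfect extractor at zero error and complete conversion — the
basis of the count-level extraction test.

What the generator does **not** emulate: PCR duplicates and amplification
bias, primer artifacts, quality-score error profiles, paired-end overlap,
indels, strand-merged CpG calling, and any non-uniform (litter- or
colony-structured) age distribution. Passing tests therefore demonstrate
correctness of the quantification and modelling machinery under the stated
statistical assumptions, not robustness to those real-data artifacts.

## Extraction

Reads are assigned in bisulfite space: every reference cytosine outside CpG
context is collapsed to T (it is always converted), CpG cytosines are C/T
wildcards, and the read goes to the region of minimum Hamming distance under
that matching (length differences count as mismatches). A best distance above
⌈0.1 × read length⌉ discards the read; ties go to the lowest region index
with a warning. Counting increments the methylated count on C and the
unmethylated count on T at each CpG offset; any other base (error or a short
read) contributes to neither — counting an N or A/G as unmethylated would
bias fractions downward with sequencing error.

The coverage rule is strict: coverage < 50 is discarded, so exactly 50 is
retained. The filter recomputes the missing flag from the counts, making it
idempotent and monotone in the threshold. Coordinates follow the de facto
dialects: BED is 0-based half-open; per-CpG coverage files
(`scaffold start end percent n_meth n_unmeth`) and site ids
(`scaffold:pos`) are 1-based. Real data enter either as coverage files or as
a fraction-matrix TSV plus sample sheet; re-running a genome-scale bisulfite
mapper is out of scope for an amplicon design.

## aDMP screening

Per site, OLS of methylation on age gives the drift slope; the p-value is the
two-sided t-test on that slope with n − 2 degrees of freedom (equivalent to
the Pearson correlation test for simple OLS). Missing cells are dropped
pairwise; fewer than 3 pairs makes a site unusable, and zero variance yields
slope 0 with p = 1. Because single-site prediction errors are conventionally
reported in weeks, RMSE/MAD/MAE come from the *inverse* regression (age on
methylation), in-sample. Selection keeps sites with p < 0.05 — strict
inequality, no multiple-testing correction, matching the published selection
style for small targeted panels — ordered by ascending p-value. MAD here is
the mean absolute error and MAE the median absolute error, following the
clock literature's (admittedly idiosyncratic) abbreviations.

## The elastic-net clock

The clock minimizes

    (1/2n) Σ_i (y_i − β₀ − x_iᵀβ)² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)

by cyclic coordinate descent over the Gram matrix, JIT-compiled, with
warm-started regularization paths. Predictors are standardized to unit
population variance within each training set (penalty fairness across CpGs);
weights are reported back on the original fraction scale. Ages are regressed
untransformed in weeks, since all errors of interest are in raw weeks.
α defaults to 0.5 (an equal L1/L2 mix, the multi-tissue-clock convention) and
is exposed as a parameter. λ is chosen by cross-validated MSE on a 100-point
log grid descending from λ_max = max_j |x_jᵀ(y − ȳ)|/(nα) to λ_max·1e-4,
with leave-one-out folds (deterministic at n ≈ 24, no random fold
assignment) and the one-standard-error rule; ties resolve toward more
shrinkage. Missing fractions are imputed with training-set per-site means, so
prediction still works when a site drops below coverage in a new sample.
Predictions are not clamped; a negative predicted age is reported as-is.

Leave-one-out cross-validation refits *everything* per fold — imputation
means, standardization, λ (re-selected by internal LOO on the n − 1
samples) and weights — so no information from the held-out sample reaches its
own prediction; a leakage test corrupts a held-out age and asserts its
prediction is unchanged.

Numerical choices: convergence is declared when the largest absolute
coefficient change in a sweep falls below the tolerance — 1e-8 for direct
fits, and 1e-5 × sd(y) inside cross-validation, where coefficients live on
the response scale and CV error curves are insensitive far below that.
Non-convergence raises with the last delta rather than returning silently. A
degenerate response (all ages equal) short-circuits to the constant-mean
model. Constant or empty feature columns are dropped with a warning before
fitting. For α → 0 the λ_max formula is floored at α = 1e-3, the usual
ridge-limit convention.

## Tissue ageing rate

The rate of a test tissue relative to the training tissue is the OLS slope of
predicted on actual age, with a t-based 95% CI; the CI excluding 1 is
reported as evidence that the tissue's clock sites drift at a different rate.
With the simulator's default skin multiplier of 0.6, a liver-trained clock
recovers a slope near 0.6 — slightly below, because baseline-driven
intercept mismatch and shrinkage flatten the mapping — and the interval
excludes 1 in essentially every replicate.

## Problem sizes

The test suite and the acceptance script use the study-scale geometry
(12 amplicons / 51 CpGs, cohorts of 24 + 19 liver and 20 skin) throughout.
Read-level simulation runs at 200× coverage; the screening/clock recovery
studies average 20 independent replicates and use binomial count sampling at
200× in place of read-level simulation, which is statistically equivalent for
count-level behaviour (the equivalence itself is exercised by the
extraction tests). Null-calibration uses 2,000 no-drift sites at n = 24.

## Known limitations

- The linear drift model has no plateau; very long-lived samples at
  steep-slope sites can clamp at 0/1, attenuating the fitted slope.
- Uniform ages overstate the leverage available in real colonies, where ages
  cluster; synthetic accuracy metrics are accordingly optimistic relative to
  published clocks on real cohorts.
- Assignment assumes amplicon-anchored reads starting at the region start;
  it is not a general aligner and does not handle indels.
- Only one bisulfite strand is modelled; strand-merged CpG calling is not
  implemented.
- The ageing-rate contrast assumes a shared linear clock between tissues and
  attributes all slope change to rate, not to tissue-specific baselines.
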