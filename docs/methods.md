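# Methods

## Scoring and segregation

The arousal score z-normalizes each post-stress ASR session (% of
pre-trauma baseline) against a reference population and averages the two
session z-scores. Defaults, both configurable:

- **Reference population = controls.** Controls define the unstressed
  norm; `stressed` and `all` are also supported since protocols differ
  on this point.
- **Session aggregation = mean of per-session z-scores** (`mean_of_z`);
  `z_of_mean` (z of the mean % change) is the alternative.
- **Threshold = 1.0, inclusive**: a score of exactly 1 is susceptible.

Composite scores are equal-weight means of sign-oriented z-scores:
avoidance-like = mean(open field, elevated plus maze), social memory =
the 5-trial social-memory measure, PTSD-like = mean(arousal, avoidance,
social memory). The raw behavioral units in the generator are oriented
so lower = more PTSD-like (center time, open-arm time, discrimination
index), hence the orientation map is −1 for all three measures; real
data with other conventions only needs a different map. Equal weighting
is a deliberate choice: without a fitted loading model it is the only
weighting that does not privilege one assay.

## Relative quantification

Triplicates are averaged on the Ct scale (not the RQ scale), because Ct
is the measurement scale on which replicate noise is approximately
additive; a replicate SD above 0.5 cycles raises a QC flag (customary
qPCR practice) without excluding the value. ΔCt uses GAPDH (mRNAs) and
U6 (miRNAs). The calibrator ΔCt per (area, analyte) is the **mean ΔCt of
the control group**, which makes the control geometric-mean RQ exactly 1
— the convention that matches group plots normalized around controls.
No amplification-efficiency correction is applied (pure 2^−ΔΔCt form).

## Group statistics

- Normality: D'Agostino–Pearson omnibus K² (undefined below n = 8, an
  explicit error).
- One-way ANOVA with explicit degenerate handling (all-equal groups:
  F = 0, p = 1; zero within-variance with distinct means: F = ∞, p = 0).
- Post hoc: Tukey–Kramer — the study's groups are unbalanced (12/7/11
  and 6/5/5) — with q referred to the studentized-range distribution
  with (k, N − k); the CDF is evaluated numerically by scipy to well
  below 1e−6 absolute error, and the in-package procedure is
  cross-checked against an independent implementation in the tests.
- Pearson r with the two-sided t-based p on n − 2 df. Correlation
  matrices report the lower triangle with the usual star codes
  (* p < 0.05, ** p < 0.01, *** p < 0.001), no multiplicity correction
  (matching how such tables are conventionally printed), and mark pairs
  with fewer than 3 complete observations "NC".
- Expression correlation tables pool all mice with data in the area by
  default (configurable to stressed-only); score correlations and score
  regressions default to stressed mice only, since the composite scores
  are designed to spread the stressed population.

## Synergic regression search

OLS with intercept; the reported model p is the overall F-test — the
standard single-number summary when only R, R² and p are printed.
Admissibility of a miRNA as predictor for a target defaults to
**strict** (sample r against the target < 0 in that area, the
repression-consistent direction) with a **permissive** mode that keeps
all four; both exist because published model tables and the stated
filter can disagree, and the ledger of every fitted subset is always
emitted so users may re-filter or correct for multiplicity post hoc (the
search itself applies no correction). Ties in R are broken toward the
lexicographically smallest predictor set; subset sizes that exceed the
pool, or models the sample size cannot support (n ≤ k + 1), are skipped
with a log notice rather than fitted.

## Regulator overlap

Exact set intersection after whitespace trimming, case-sensitive.
Because only the *shared* regulator lists are public, the packaged
fixture set for each miRNA is the union of its printed pairwise shared
lists plus miRNA-unique `DECOY_*` padding; this reconstruction provably
reproduces every printed pairwise intersection (verified cell by cell)
while keeping the intersection operation non-trivial.

## Pathway enrichment

One-sided upper-tail hypergeometric (Fisher exact) per pathway,
Benjamini–Hochberg step-up across all pathways tested. The default
background is the union of all pathway genes — web-tool backgrounds are
irreproducible, so the choice is explicit and overridable. Target genes
outside the background are dropped with a warning. The packaged GMT and
target list are synthetic fixtures (named accordingly) with two planted
enriched pathways; they stand in for database-exported target lists,
which are out of scope to regenerate.

## The synthetic cohort generator

The generator emulates the study design, not any particular dataset:

- **Cohort**: 12 control / 18 stressed mice dissected for HIP + mPFC
  and 6 / 10 for HT (46 in total), overridable.
- **ASR model** (% of baseline, per session): controls N(100, 15);
  stressed mean 109 with between-session SD 8 and a coupling of
  9 percent-points per SD of a latent susceptibility trait
  λ ~ N(0, 1). These defaults were calibrated once, by direct
  simulation of the scoring rule, so that threshold segregation yields
  on average ≈ 30% susceptible stressed mice — the yield the protocol
  is designed to deliver (25–35%); they were then frozen.
- **Behavioral measures**: N(100, 15) controls, stressed shift −8 with
  coupling −6·λ (arbitrary units; lower = more PTSD-like).
- **Expression**: Gaussian on the ΔCt scale (log2-linear in expression,
  the standard qPCR noise model), per-analyte biological SD 1 cycle,
  analyte–analyte correlation matrices per area (positive among miRNAs;
  negative miRNA:FKBP5 in HIP and HT; near-zero couplings in mPFC), and
  per-phenotype mean ΔCt shift profiles whose directions follow the
  reported group effects. A stressed mouse's shift interpolates between
  the resilient and susceptible profiles linearly in λ, so the same
  latent trait drives both behavior and expression; λ itself is never
  visible to the analysis — phenotypes come only from the arousal
  threshold.
- **Technical layer**: per-mouse/area RNA-loading offset N(0, 0.3)
  added to every analyte including references (cancels in ΔCt),
  reference noise SD 0.1, triplicate Ct noise SD 0.15 cycles. All
  emitted numbers are rounded to 6 significant digits, which is also
  the file format precision, so written cohorts round-trip exactly.

What the generator does **not** model: stress physiology (corticosterone,
immune markers), sex effects (the emulated design is male-only), floor/
ceiling effects in behavioral assays, PCR efficiency differences between
analytes, plate/batch effects, and missingness. Tests passing on this
generator therefore validate the *analysis machinery* — scoring rules,
quantification algebra, statistics, search and set operations — not
biological claims about real cohorts.

## Calibration checks and their scales

Two simulation-based checks are scale-sensitive and are deliberately run
on the additive (log) scale where the generative model is exactly
Gaussian:

- **Planted-correlation recovery** is measured as the Pearson r of
  log2(RQ) values. The planted parameter is a ΔCt-scale correlation;
  on the raw RQ scale the log-normal transform attenuates Pearson r
  (a planted −0.6 measures ≈ −0.55 at the default SDs), which would
  conflate transform bias with estimation error. Replicate and
  reference noise still attenuate the measured correlation slightly
  (expected ≈ −0.585 for a planted −0.6).
- **Null ANOVA calibration** uses ΔCt values. On RQ (log-normal) the
  F-test is conservative in small skewed groups (empirically ≈ 0.026
  at nominal 0.05), which is a property of applying ANOVA to skewed
  data, not of the machinery under test; on ΔCt the empirical rate is
  ≈ 0.04–0.05 as it should be.

## Problem sizes

The test suite and acceptance script use: 200 simulated cohorts for the
segregation-yield average, 100 replicates at n = 200 for correlation
recovery, 500 cohorts for the null ANOVA rate, 200 random 6-predictor
problems for the best-subset/brute-force comparison, and 300 random
tables (background ≤ 500) for the exact Fisher-tail comparison — sizes
at which the Monte-Carlo error of each check is comfortably below its
acceptance band.

## Known limitations

- The composite-score weights and the z-reference population are
  conventions, not estimates; alternative choices change labels near
  the threshold.
- The strict admissibility filter uses the *sample* correlation sign,
  so predictors near r = 0 enter or leave the pool by sampling noise.
- Enrichment treats pathways independently; overlapping gene sets make
  BH control approximate in the usual way.
- The generator's single latent trait makes susceptibility
  unidimensional; real phenotypes are unlikely to be.
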