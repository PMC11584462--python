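# Methods

## The problem

Point dendrometers record stem radius at sub-hourly resolution for years at
a time, and fail for days to months at a time: batteries die, loggers fill
up, sensors are knocked, animals chew cables. The resulting gaps are the
main obstacle to intra-annual growth analysis — especially when they fall
inside the growing season, and especially for isolated or urban trees where
no well-correlated neighbour exists to borrow data from.

`dendrogap` implements a gap-filling workflow whose core idea is that
*cumulative* stem growth — not the raw radius — is predictable from purely
temporal covariates. The raw radius mixes irreversible growth with a large
reversible diurnal shrink–swell signal driven by tree water status; the
cumulative-growth component alone is a smooth, monotone function of the
calendar that a regression model can learn from the intact parts of a
record and extrapolate into gaps of 30 days and more, without climate data
and without neighbouring trees.

## Pipeline

1. **Quality control** (`preprocess`). Air temperature is screened by a
   physical range ([−40, 50] °C) and a spike rule (> 10 °C against both
   neighbours). Dendrometer *jumps* — abrupt sensor shifts from technical
   disturbance — are detected as first differences exceeding
   `diff_threshold_mad` (default 10) × MAD of all first differences, and
   corrected by subtracting the offset from all later values (a `delete`
   mode blanks the segment instead). A *frost guard* refuses to correct
   negative steps coinciding with air temperature ≤ 5 °C: frost-induced
   stem shrinkage is real signal, not sensor error. Missing runs of at
   most 24 points (12 h on the half-hourly grid) with observed flanks are
   linearly interpolated; longer runs are left for the model.

2. **Zero-growth extraction** (`growth`). With `M(t)` the running maximum
   of the cleaned radius, cumulative growth is `G(t) = M(t) − radius(t₀)`
   and tree water deficit is `TWD(t) = M(t) − radius(t)`, so
   `radius = radius(t₀) + G − TWD` exactly at every observed point. G is
   non-decreasing, TWD ≥ 0, and missing slots propagate (no implicit
   interpolation). Because the model attributes any new maximum to growth,
   winter bark-swelling artifacts can masquerade as off-season growth; the
   winter correction cancels positive G increments at DOY < 60 or
   DOY > 304 (configurable; a strict mode blanks those rows).

3. **Features** (`features`). Predictors are day of year (1–366, no
   leap-year rescaling), calendar year (integer), and fractional hour
   (13.5 for 13:30). Grouped multi-tree models add per-tree constants:
   unsealed ground area (m², capped at 144 — the cap represents a fully
   unsealed site) and, for non-urban groups, tree height. Collinearity is
   screened by iterative VIF removal at threshold 5 (on calendar grids the
   temporal features are almost orthogonal; max VIF ≈ 1). A Uniform(0,1)
   "random" column can be appended as the no-importance baseline for
   permutation feature importance.

4. **Model fitting** (`gapfill`). Non-gap rows are split 80/20 into
   training and test subsets by stratified sampling on (year, hour), so
   both subsets see every season-of-day cell. All features are z-scored
   with parameters estimated on the *training subset only*; the same
   parameters transform test and gap rows — this is the leakage boundary,
   and it is asserted by recomputation in the tests. The default regressor
   is gradient-boosted trees (XGBoost); random forest, k-nearest-neighbour
   and ridge are registered for comparison, and the registry accepts
   plug-ins. Performance is reported as RMSE and adjusted
   R² = 1 − (1−R²)(n−1)/(n−p−1).

5. **Gap prediction**. Gap rows are normalized with the stored training
   parameters and predicted; predictions are flagged `ml_fill`, and rows
   whose features fall outside the training ranges are additionally marked
   `extrapolated`. Predictions are deliberately *not* forced monotone:
   a declining cumulative-growth fill is a model failure the user must
   see. `sanity_check` surfaces (a) declines persisting longer than one
   day, (b) discontinuities against the flanking observations beyond a
   configurable threshold (default 50 µm), and (c) negative values — and
   never mutates the data.

## Why shallow boosted trees

Default hyperparameters: 300 rounds, learning rate 0.1, **max_depth 2**,
early stopping after 20 rounds without validation improvement (validation
= a random 20% of the training subset; a flag switches to training-set
stopping). No tuning is applied by default.

The depth choice is the one place where gap filling differs from ordinary
curve fitting. Filling a 30-day window means predicting a (year × DOY)
cell that contains *no training data*. Deep trees partition exactly along
such cells and extrapolate each cell from whatever leaf happens to border
it; on synthetic 5-year trees, depth-6 models missed the growth onset
inside blanked spring windows by ~160 µm RMSE (a third of the annual
amplitude) while fitting the observed rows essentially perfectly. Shallow
trees force a near-additive decomposition f(DOY) + g(year) + h(hour),
which transfers the seasonal shape shared across years into the unseen
window (~25 µm under the same conditions, ahead of the spline baseline's
35 µm). Cumulative growth really is close to additive in these
coordinates — one amplitude per year plus a common seasonal shape — so the
restriction costs little on observed data and buys the cross-year transfer
the method depends on. Users fitting short single-year records with dense
coverage may prefer deeper trees via `hyperparams={"max_depth": ...}`.

`tune_model` provides the optional search path: candidates scored by
k-fold CV RMSE, ~10 random draws, then a Gaussian-process surrogate with
lower-confidence-bound acquisition for the remaining iterations (default
budget 70). The default configuration is always scored as a reference
candidate, so tuning can only improve the CV RMSE. It is not part of the
default pipeline: early stopping already controls overfitting, and the
search multiplies the cost by k × iterations.

## Baselines and benchmark

- **Spline**: a cubic smoothing spline fitted to 5 days of observations on
  each flank, evaluated inside the gap. It cannot represent a step-like
  onset inside the gap and will happily produce decreasing or negative
  "growth" — reproduced (not suppressed) in the tests, because surfacing
  that failure mode is the point of the comparison.
- **Network interpolation**: the target is regressed (OLS with intercept)
  on the best-correlated reference tree over their common observed span;
  eligibility requires a reference with *no* missing values inside the gap
  and Pearson r ≥ 0.5. When no reference qualifies the result is "not
  applicable" — a recorded outcome, not an error, because the
  applicability rate is itself a finding. A config option averages all
  qualifying references instead of using the single best.

The benchmark blanks three fixed 30-day windows per year — start
(Apr 16 – May 15), middle (Jun 1 – 30), end (Sep 1 – 30) — in every
dataset, retrains each ML method from scratch on everything outside the
window, and scores all methods by RMSE against the withheld truth on the
half-hourly grid (the label's native resolution; daily averaging would
flatter all methods equally). An in-code assertion guarantees no training
row lies inside the blanked window. Method RMSEs over common
(dataset, window) blocks are compared with the classical Friedman
chi-square test (within-block ranks, mean ranks for ties, χ²(k−1)
p-value) and pairwise two-sided Mann–Whitney U tests (exact p by
enumeration for n ≤ 12 without ties, tie-corrected normal approximation
otherwise). p-values are reported, never enforced, and no multiple-testing
correction is applied. Note the chi-square p is an approximation: on very
small designs (≤ 10 cells) it can differ from the exact permutation
p-value by up to ≈ 0.28, which matters if the benchmark is run with only a
handful of blocks.

Permutation feature importance is computed on the test rows by default
(configurable): PFI = mean over 50 permutations of
R²(original) − R²(permuted). Values above 1 indicate the permuted model's
R² went negative; the random baseline feature brackets "no importance".

## The synthetic generator

`simulate` stands in for field data. Cumulative growth follows a symmetric
double sigmoid in day of year,
`G(d) = A/2·[σ(k(d−onset)) + σ(k(d−cessation))]`, accumulating one
amplitude A per year; the midpoint between onset and cessation sits at
exactly A/2. Defaults: A = 500 µm, onset DOY 110, cessation DOY 280,
steepness 0.12 d⁻¹ — a mid-range temperate broadleaf season; steepness
0.5 d⁻¹ is used in tests as the "abrupt onset" condition. TWD is a
non-negative diurnal profile (zero at night, peak mid-afternoon, default
amplitude 60 µm) tapered by growing-season activity; sensor noise is
Gaussian (default sd 2 µm, a realistic point-dendrometer resolution
floor). Jumps add a step offset from an instant onward; gaps blank
configured runs; frost episodes force sub-threshold temperatures in the
climate stream. Each tree draws from its own random stream derived from
(seed, tree id), so adding trees never perturbs existing ones and every
output is bit-reproducible from the seed.

`simulate_network` blends each tree's half-hourly growth increment as
`rho·common + (1−rho)·individual`, where the common part is the
deterministic seasonal curve and the individual part is a random
non-negative process (daily exponential weights normalized to the same
annual amplitude). rho = 1 gives identical shapes; rho = 0 gives
uncorrelated *increments*. Note that cumulative *levels* remain correlated
across trees at any rho (all curves rise by A per year) — which is exactly
why the network baseline's correlation gate is probed with genuinely
uncorrelated references in the tests rather than with rho alone.

What the generator does **not** emulate: climate-driven growth variation
(growth responds to the calendar only), precipitation or soil moisture,
drought-year TWD anomalies, bark-swelling winter artifacts, multi-sensor
inconsistencies, or heteroscedastic sensor drift. Passing tests therefore
show that the pipeline recovers structure *of the kind it assumes*; they
do not show that real trees are this predictable. In particular the
benchmark's absolute RMSE values are properties of the simulated
conditions, not of any field dataset.

## Problem sizes and numerical choices

- Test-suite experiments use half-hourly grids over one to five years
  (17.5k–87.6k rows per tree); the benchmark-design check runs the full
  16-dataset × 15-window × XGB layout (240 fits, ≈ 4 min on one CPU); the
  acceptance script uses a 6-tree, 3-year network (8 datasets × 9 windows
  × 3 methods, ≈ 1 min).
- Stratified split rounding: per-stratum training count =
  ⌊0.8·n + 0.5⌋, at least 1; singleton strata go to training with a
  warning.
- z-normalization uses the population sd (ddof 0); zero-variance columns
  are a caller error, and constant columns (e.g. `year` in a single-year
  dataset) are dropped before modelling with `drop_constant_columns`.
- VIF ties are broken by removing the later column in declaration order;
  perfect collinearity maps to VIF = ∞.
- Jump detection falls back from MAD to the mean absolute deviation when
  the MAD of first differences is exactly zero (near-constant series).
- The zero-growth reference r₀ is the first *non-missing* radius value.
- Degenerate inputs raise typed errors (`errors` module): all-missing
  series, disjoint spans, off-grid or duplicate timestamps, empty test
  sets, fewer training rows than features.

## Known limitations

- Offset-subtraction jump correction estimates the offset from a single
  noisy first difference; stacked jumps inside one detection window are
  corrected sequentially and may leave residual level error of order the
  noise sd.
- The ML filler cannot anticipate growth patterns absent from the training
  years (e.g. an exceptionally early onset in the gap year); such fills
  look plausible but are biased toward the typical year. This is inherent
  to calendar-only predictors, and is why `sanity_check` plus visual
  inspection remain part of the workflow.
- Raw radius series (growth + TWD mixed) are out of scope as a prediction
  target; the method fills the cumulative-growth component only.
- The Friedman p-value is asymptotic (see above); for tiny benchmarks
  prefer the pairwise exact Mann–Whitney tests.
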