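# Methods

## Scope and model

`ppdp` balances a two-class numeric table by deleting unrepresentative
majority rows and synthesizing minority rows from fitted distributions.
It assumes: exactly two classes; all features numeric and finite;
features treated independently by every sub-model (fences, MTD domain,
Weibull fit are all univariate); and a minority class of at least three
rows (the smallest sample for which the Gini-spacings test is defined).

## Undersampling

**Fence stage.**  Quartiles default to Tukey hinges — the median of the
lower/upper half of the sorted sample, halves including the overall
median when n is odd.  The convention matters at small n (the reference
counts of the whole pipeline shift slightly under interpolated
percentiles), so it is exposed as `quartile_convention` with a
`"linear"` alternative.  A row is deleted when *any* feature falls
outside its inner fences: feature-wise rules must be aggregated to row
level for the majority count M′ to be well defined, and the union rule
is the only aggregation that removes a row exactly when something about
it is suspect.

**MTD stage.**  The diffusion constant is ln 10⁻²⁰ ≈ −46.05; the domain
half-widths scale as `s/√N_L` and `s/√N_U`, so the estimated domain is
generous for very small samples (the regime mega-trend diffusion was
designed for) and *narrower than the observed range* once N is a few
dozen.  Consequences accepted deliberately:

- The α-cut is a genuine undersampler at moderate N: for a unimodal
  feature at α = 0.5 it retains roughly the central 35–45% of mass,
  whatever the distribution, because the fence stage has already trimmed
  the tails that would otherwise inflate the variance.
- Observed values can lie outside [a, b]; they get membership 0 and are
  removed at any α.  A warning is emitted when this happens.
- The domain is fitted on the fence-stage survivors, not the raw
  majority.

Ties at `u_set` count in neither N_L nor N_U (the counts are defined by
strict inequalities).  Because `u_set = (min+max)/2`, N_L = 0 can only
happen when min = max, i.e. for a constant feature; both fallback bounds
(`a = min/5`, `b = 5·max`) then apply together.  Constant (zero-variance)
features yield a degenerate, point-mass membership; the resampler skips
the α-cut for them rather than keeping only exact ties.  The lower bound
is *not* clipped at zero for nonnegative data; the formulas are applied
literally.

## Oversampling

**Shape by maximal p-value.**  The candidate grid is β₀ ∈ {0.05, 0.10,
…, 10.00} followed by one refinement pass at step 0.005 around the
coarse maximizer.  The grid brackets the exponential (β = 1) through
near-normal (β ≈ 3–4) shapes generously; the refinement makes the
resolution fine enough that round-trip tests recover a generated β to
one coarse cell.  p-value plateaus are broken by the smaller linearized
SSE, then the smaller β — deterministic, and biased toward parsimonious
(more exponential-like) shapes.  The test is two-sided:
`p = 2·min(F(g), 1−F(g))` with the exact null CDF for 3 ≤ N ≤ 20 and the
normal approximation `z = √(12(N−1))(g − ½)` beyond.  The exact CDF is
evaluated in double precision with pairwise products of the
`c_j = (N−j)/(N−1)` differences; for N ≤ 20 this is well conditioned, and
a 200,000-replicate Monte Carlo (exponential-spacings construction) is
the regression oracle.

**Support shift.**  The Weibull needs strictly positive data.  Strictly
positive inputs are fitted as-is (shift 0).  If min ≤ 0, the sample is
shifted by `min − 0.01·range`; a zero-range (constant) sample uses
`min − 1` and fits degenerately rather than erroring, since the pipeline
tolerates constant features elsewhere.  The shift is recorded in the fit
and added back on generation.  Note that a *shifted* Weibull sample with
strictly positive minimum is fitted without shift, and the
two-parameter family then absorbs the offset into a larger shape — the
fitted quantiles still track the sample, which is what synthesis needs,
but the shape parameter itself is only interpretable when the support
truly starts near zero.

**Generation.**  Median-rank inversion is deterministic per feature and
ascending in the rank; applying it verbatim to all P features would make
every synthetic row a joint quantile (all features comonotone).  The
default `permuted` mode therefore shuffles each synthetic column
independently with the seeded generator, preserving each marginal
multiset while breaking the artificial coupling; `median_rank` keeps the
literal ordering for reproducing the formula exactly.  The minority fit
uses all minority rows — no outlier removal is applied on the minority
side.

## Pipeline contracts

`M′ = M − S_box − S_mtd`, synthetic count `max(M′ − m, 0)`,
`m′ = m + synthetic`.  If undersampling leaves M′ ≤ m, no synthesis
occurs and a warning is emitted.  A single seed drives all stochastic
choices; equal seeds give bit-identical outputs.  Retained majority
counts are non-increasing and S_mtd non-decreasing in α (nested α-cuts);
total removal at high α raises an error telling the user to lower α.

## Synthetic data generator

The generator emulates a small clinical table: four numeric features for
the majority class driven by one latent severity factor
(`X_j = loc_j + scale_j·(√ρ·Z + √(1−ρ)·E_j)`, ρ = 0.95 by default) with
an `outlier_rate` = 0.05 fraction of rows given one feature displaced
beyond 10 IQR, and a minority class drawn from genuine per-feature
Weibulls (β between 1.5 and 2.5, shifted to overlap the lower range of
the majority).  The strong latent correlation is essential realism, not
decoration: real panels (morphometric or biochemical readouts of one
underlying condition) are near-collinear, and the undersampler's
any-feature union rule would otherwise compound per-feature removal
rates multiplicatively and delete everything.  What the generator does
*not* emulate: discrete/ordinal features, missingness, label noise,
class overlap structure beyond a location shift, and heavy-tailed
majority marginals — passing tests show the pipeline's contracts and
estimator calibration, not performance on any particular clinical
dataset.

Scenario splits follow the r×N design: m = round-half-up(r%·N) floored
at 3, M = N − m, drawn without replacement; the remainder of the source
data is the test set, redrawn per repetition.  Round-half-up is the only
rounding consistent with (M, m) = (142, 8) at r = 5, N = 150.  The
default downstream classifier is a polynomial-kernel SVM (degree 2,
C = 1); any sklearn-style estimator can be passed instead.

## Problem sizes and numerical checks

The test suite and the acceptance script use: 200,000 null replicates
for the exact-CDF decile check (tolerance 0.01), 5,000 replicates for
test calibration at nominal 10% (accepted band 8–12%), 200 replicates of
N = 100 for parameter recovery (median β̂ in [1.35, 1.65], median λ̂ in
[1.8, 2.2]), 50 random samples for the closed-form scale estimator vs a
bounded 1-D numeric minimizer (relative gap ≤ 10⁻⁶; the closed form is
the analytic minimizer, so the observed gap is at machine precision),
and 50-repetition classifier comparisons at (r, N) = (5, 60).  The whole
suite runs in well under a minute on one core.

## Known limitations

- The α-cut undersampler is aggressive at moderate-to-large M; with
  several weakly correlated features M′ can collapse to a handful of
  rows, and at α ≥ 0.7 to zero (an error by design).
- Shape estimation on shifted-support data inflates β (see above).
- Only binary classification, numeric features, in-memory tables.
- The exact Gini CDF is limited to 3 ≤ N ≤ 20 by construction; beyond
  that the normal approximation is used, which is standard but slightly
  liberal at N just above 20.
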