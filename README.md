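# ppdp — distribution-aware resampling for imbalanced two-class tables

Small biomedical classification tables are routinely imbalanced: the
patients of interest (the *positive*, minority class) may be a few percent
of the rows, and classifiers trained on the raw table learn to predict the
majority everywhere — high accuracy, useless sensitivity.  `ppdp`
implements a pre-processing pipeline that balances such a table before any
classifier sees it, by **representative undersampling** of the majority
class and **distribution-fitted oversampling** of the minority class.

## The method

Given a training table with M majority and m minority rows over P numeric
features:

1. **Fence screening.**  Per feature, rows outside the Tukey inner fences
   `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` (quartiles as Tukey hinges) are deleted
   as suspected outliers (`S_box` rows; a row is deleted if *any* feature
   violates its fences).
2. **Mega-trend-diffusion (MTD) α-cut.**  Per feature, the plausible
   domain `[a, b]` of the surviving sample is estimated by
   variance-scaled, skewness-weighted diffusion about
   `u_set = (min + max)/2`:

       a = u_set − S_L · sqrt(−2 s² / N_L · ln 10⁻²⁰)
       b = u_set + S_U · sqrt(−2 s² / N_U · ln 10⁻²⁰)

   with `N_L`, `N_U` the counts below/above `u_set` and
   `S_L = N_L/(N_L+N_U)`, `S_U = 1 − S_L`.  A triangular membership peaks
   at `u_set` and vanishes at `a`, `b`; rows outside the α-cut
   `A_α = [(u_set−a)α + a, b − (b−u_set)α]` in any feature are deleted
   (`S_mtd` rows, default α = 0.5), leaving `M′ = M − S_box − S_mtd`
   representative majority rows.
3. **Weibull oversampling.**  Each minority feature is fitted with a
   two-parameter Weibull.  The shape β is chosen by *maximal p-value*: for
   each candidate β₀ the Gini statistic on the weighted spacings
   `W_i = (N−i+1)(x₍ᵢ₎^β − x₍ᵢ₋₁₎^β)`,

       G_N = Σ i·W_{i+1} / ((N−1) Σ W_i),

   is tested against its null distribution (exact CDF for 3 ≤ N ≤ 20,
   normal approximation `√(12(N−1))(G_N − ½)` beyond), and the β₀ with the
   largest two-sided p-value wins.  The scale λ then has a closed form
   from least squares on the linearized CDF with Bernard's median ranks
   `F̂ᵢ = (i − 0.3)/(N + 0.4)`.  `M′ − m` synthetic rows are generated by
   median-rank inversion `x̂ᵢ = λ(−ln(1 − F̂ᵢ))^{1/β}`.
4. **Merge** into a balanced table with `M′` rows per class.

Evaluation uses accuracy, `G-mean = √(TPR·TNR)` and F1 — the latter two
are the informative ones under imbalance.

## Worked example

```python
from ppdp import PPDP, fixtures

ds = fixtures.make_synthetic_imbalanced(fixtures.FixtureSpec(seed=3))
train, test = fixtures.make_scenario(ds, fixtures.ScenarioSpec(r=5, n_train=60, seed=1), 0)
res = PPDP(train.features, train.labels, train.feature_names, positive_label=1).fit(alpha=0.5, seed=42)
print(res.summary())
```

```
PPDP resampling results
=======================================================
alpha-cut: 0.5      seed: 42
majority M:             57
  removed by fences:    6
  removed by alpha-cut: 47
  retained M':          4
minority m:             3
  synthetic added:      1
  extended m':          4
-------------------------------------------------------
minority Weibull fits (per feature):
feature    beta   lamda  shift  p_value    sse
     x0 10.0500  5.1186 0.0000   0.7572 0.0925
     x1  8.4800 15.0318 0.0000   0.9998 0.5022
     x2  4.6150  2.5808 0.0000   1.0000 0.3791
     x3 10.0500 37.8648 0.0000   0.0862 1.0908
```

A 57:3 training draw is reduced to a 4:4 balanced table: 6 rows fell
outside the fences, 47 outside the α-cut (the α-cut keeps only the
central core of each feature — the method is deliberately aggressive), and
one synthetic minority row was added from the per-feature Weibull fits.
`res.balanced` holds the table; `res.report` the counts and sub-models.

The effect on a downstream classifier (polynomial-kernel SVM, degree 2,
C = 1 — the reference configuration) at 5% minority share, 50 repetitions:
training on the raw draw gives mean G-mean ≈ 0 (the SVM predicts the
majority class everywhere), training on the resampled table gives mean
G-mean ≈ 0.89 on the same test sets (`fixtures.run_experiment`).

## Command line

```bash
ppdp resample --input X.csv --label-col class --positive-label 1 \
     --alpha 0.5 --seed 42 --output balanced.csv --report report.json
ppdp fit-weibull --input column.csv
ppdp simulate --seed 3 --output data.csv
ppdp experiment --input data.csv --r 5 --n 60 --reps 50 --seed 42 --out results.csv
```

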