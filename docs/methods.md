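# Methods

`oeac` builds and evaluates cross-species epigenetic aging clocks for
toothed whales (odontocetes) from array-style DNA methylation data, and
bundles the surrounding analyses a population study needs: age EWAS,
trait classification, and demographic inference for wild samples. This
note records the models, the defaults and why they are set as they are,
and what the synthetic benchmark does and does not demonstrate.

## Age transform

Methylation drifts quickly during development and roughly linearly
through adulthood, so the clock regresses on a transformed age rather
than years. For a species with age at sexual maturity `m` and gestation
time `g` (both in years, both > 0), with `k = m + g`:

    F(x) = log((x + g) / k)   for 0 <= x <= m
    F(x) = (x - m) / k        for x > m

`F(m) = 0`, both one-sided derivatives at the knot equal `1/k`, and `F`
is strictly increasing, so the juvenile log regime joins the adult
linear regime smoothly. The inverse is exact
(`k·exp(y) − g` for `y ≤ 0`, `m + k·y` otherwise); predicted ages are
clipped below at 0, since a linear predictor can undershoot the
transform's range. The transform is isolated in one module
(`oeac.transform`), so a different functional form is a one-function
change. Per-species `m` and `g` are inputs (the species-parameter CSV);
the simulator ships typical delphinid/monodontid values, but users of
real data should supply their own life-history table.

## Clock fitting

The clock is a LASSO (`alpha = 1`) linear model on beta values with the
per-sample transformed age as response, solved by coordinate descent
(scikit-learn's `lasso_path`) under the objective

    (1/2n) * sum_i (y_i - b0 - x_i . beta)^2 + lambda * ||beta||_1 .

Predictors are standardized to unit variance internally and coefficients
reported on the original beta scale, matching the behaviour of the
penalized-regression tooling standard in this field. The penalty is
chosen by internal 10-fold cross-validation as the minimizer of mean CV
squared error over a descending geometric grid (ties go to the sparser,
larger lambda). We use the minimum-CV rule rather than the 1-SE rule:
the selection is described as automatic internal CV, and minimum-CV is
the default of that workflow.

Numerical choices:

* **Lambda grid.** 40 values from `lambda_max` (the smallest penalty
  that zeroes every coefficient, computed on standardized predictors)
  down to `0.03 * lambda_max`. On the synthetic benchmark the selected
  lambda sits well inside this range; tests that need near-interpolation
  (noiseless planted-truth recovery) pass a deeper grid explicitly.
* **Solver tolerance.** `tol = 1e-3`, `max_iter = 500` per path. This is
  looser than the library default and is plenty for CV model selection;
  the precision-sensitive tests tighten it per-estimator.
* **Fold assignment** is stratified by species (a rare species is dealt
  round-robin across folds, so it cannot vanish from training folds) and
  depends only on the set of sample ids and the seed, never on input
  row order. Internally samples are re-sorted by id before fitting, so
  the fitted model is bit-identical under permutations of the input.
* **Missing betas** are imputed with the training-set probe mean, which
  is stored in the model and reused at prediction time (leakage-safe and
  recorded). The upstream question of how missing probes should be
  handled on real arrays is deliberately left to the user; the cohort
  loader accepts `NA` entries.
* **Degenerate inputs.** Constant transformed response and
  fewer-samples-than-folds raise immediately; a fully penalized grid
  (`lambda = inf`) yields the intercept-only model with
  `b0 = mean(y)`.

Prediction applies the sparse weights to the (imputed) betas and inverts
the transform with the *target sample's own* species parameters, so the
same methylation profile maps to different ages for species with
different life histories — by design.

## Cross-validation and metrics

* **LOOCV** refits the clock on `N − 1` samples and predicts the deleted
  sample, for every sample.
* **LOSOCV** deletes all samples of one species, refits on the rest and
  predicts the deleted species; it estimates accuracy for a species
  absent from training. The held-out species' parameters enter only at
  inversion.

Lambda is re-selected inside every outer fold (nested CV); nothing about
the held-out unit — ages, sex, anything — can influence its prediction,
and the test suite asserts bit-identical held-out predictions under
mutation of the held-out unit's ages.

Accuracy is summarized by the Pearson correlation `r` between DNAm age
and chronological age and the **median** absolute error in years (a
single gross miss does not move it, unlike the mean). Per-species values
and their across-species medians are reported; a species with fewer than
two predictions (or zero variance) has undefined `r` and is excluded
from the median with a warning.

## Age EWAS

Per (species, tissue) cell, each probe's Pearson `r` against
*untransformed* chronological age is computed on pairwise-complete
observations (a transformed-age variant is available behind a flag),
converted to the Fisher statistic `z = atanh(r)·sqrt(n − 3)` with a
two-sided normal p-value. Conventions:

* `z` is capped at ±40, and a numerically perfect correlation
  (`|r| > 1 − 1e−12`) is snapped to ±1 first so that exact linear probes
  hit the cap instead of landing at a rounding-determined value.
* Constant probes have undefined `r`; they are kept in the table with
  NaN statistics and never ranked.
* Top sets take probes at a nominal threshold (default `p < 1e−4`),
  ranked by `|z|` within each direction and capped (default 500 per
  direction). No multiple-testing correction is applied: the procedure
  is nominal-threshold selection with directional caps.
* All rankings break ties by `|z|` descending then probe id ascending,
  for determinism.
* Upset counts enumerate exclusive intersection regions; their sum
  equals the union size by construction and by test.
* The CpG-island contrast compares median `z` between island and
  non-island probes (percent difference relative to the non-island
  median) with a two-sided Mann–Whitney test.

## Trait classification

Species, tissue and sex are predicted by a random forest (500 trees,
Gini, `sqrt(p)` candidate features per split, unlimited depth — the
ecosystem defaults) via scikit-learn's `RandomForestClassifier`.
Accuracy is the out-of-bag error: the majority vote over trees whose
bootstrap excluded the sample, compared with the truth; samples never
out-of-bag are excluded from the denominator with a warning. Ties go to
the first class in sorted vocabulary order. Species labels are never
used as features.

The sex-dimorphic CpG scan is a per-probe Welch two-sample t-test of
beta values between females and males (robust to unequal group sizes),
ranked by p with probe-id tie-breaks; direction is the sign of
`mean_M − mean_F`.

## Demographics

Life-history categories use strict boundaries (an animal exactly at a
cut stays in the younger class): females are juveniles to 9 y, adults to
40 y, post-reproductive beyond; males are juveniles to 13 y, adults to
40 y, aged beyond. Unknown sex is "unclassified" and excluded from sexed
percentages. Two exact tests:

* **Sex ratio**: one-sided exact binomial against 1:1 toward the
  majority sex, `P(X ≥ max(m, f))` under `Binomial(m + f, 1/2)`. The
  one-sided form is the one consistent with the reference calculation
  for a 31:13 skew (p ≈ 0.005); it is symmetric in its arguments.
* **Absent class**: for a class with reference population proportion
  `p`, the expected count in a sample of `n` is `n·p` and the
  probability of observing none is `(1 − p)^n` — the binomial mass at
  zero.

## Synthetic cohorts

The generator emulates the structure of a multi-species odontocete
methylation panel with full ground truth. Default scale: nine species,
424 samples (four species contribute both blood and skin; the rest one
tissue), ages spanning 0–58 y with species-specific ranges and
life-history parameters, 2000 probes. Planted probe classes: 50 shared
aging CpGs (identical slope in every species — the conserved-CpG
assumption that makes a cross-species clock possible), 45 species-private
aging CpGs, 8 sex CpGs (mostly X-like, lower in males, offset 0.4), 100
tissue-offset and 100 species-offset CpGs, the rest null. Betas are

    clip01( mu + s·F(age) + tau·skin + sigma[species] + delta·male + eps )

with `mu ~ U(0.15, 0.85)`, aging slopes `|s| ~ U(0.05, 0.10)` in beta
units per transformed-age unit, tissue offsets `|tau| ~ U(0.15, 0.30)`,
species offsets `N(0, 0.08)` and noise `eps ~ N(0, 0.03)`. At these
defaults fewer than 1% of entries clip; a logit-space mode applies the
same effects on the logit scale and never clips. One seeded random
stream drives all draws in a documented order, so cohorts are
bit-reproducible.

What this does **not** emulate: array chemistry and detection noise,
batch and institution effects, probe cross-hybridization, heteroscedastic
beta noise near the boundaries, age-estimation error in the sample
sheet, and correlated CpG blocks. Passing the benchmark therefore shows
that the pipeline recovers planted structure of realistic effect size
and noise at a realistic cohort scale — it does not certify accuracy
numbers on real arrays, which face all of the above.

## Benchmark problem sizes

The acceptance benchmark runs LOOCV (424 refits with nested 10-fold
selection) and LOSOCV (9 refits) on the default cohort, which completes
in minutes on a single core with the solver settings above; the unit
suite uses three-species cohorts of ~90 samples and 60–150 probes for
everything that does not need full scale.

## Known limitations

* The transform's functional form is the standard mammalian-clock
  log-linear form; studies using a different supplement-specified
  variant should swap `oeac.transform` accordingly.
* The EWAS p-value uses the normal approximation of the Fisher z; at
  very small `n` an exact t-based p would differ slightly.
* LOSOCV medians can be dominated by species with few samples; species
  with undefined `r` are dropped from the median, which is the only
  defensible choice but should be kept in mind when comparing strata.
* The demographic category boundaries are killer-whale-specific
  conventions; other species need different cuts.
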