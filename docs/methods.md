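# Methods

## The protocols

A **cross-validation protocol** P is the tuple (grid, V, Nexp, loss): a grid
of K candidate parameter settings α₁…α_K, a fold count V, a repeat count
Nexp, and a loss function. Applying P to a dataset D means: Nexp times,
split D pseudo-randomly into V folds; for each fold fit every grid point on
the complement L and predict the held-out fold T; pool the predictions over
all of D and compute one loss per grid point; then average the Nexp losses
per point and choose the minimiser, breaking exact ties toward the lowest
complexity rank. The chosen point's model is refit on all of D.

**Nested cross-validation** assesses the model *chosen by* P. Nexp2 times,
the output is stratified and D is split into V2 stratified folds; for each
outer fold, the entire protocol P (with V1 inner folds and Nexp1 inner
repeats) runs on the outer training set alone, the winning model is refit
there and applied to the outer held-out fold; the pooled loss over D is one
nested CV error. The mean of the Nexp2 errors is the P-estimate of the
large-sample error; their min–max range is the P-estimated interval. The
headline report is mean, min and max — the repeat-to-repeat variability is
large enough that a single number misleads — with quartiles available via
`summarize_repeats`. Two protocols scanning different grids over the same
learner produce different P-estimates; results therefore carry a protocol
identifier, and comparing estimates across protocols is a user decision,
not something the package hides.

**Selection with variable screening** treats the number of kept variables n
as one more grid axis: the grid is the product of candidate n values and the
α grid, and within every fold the selector ranks descriptors by |Pearson r|
against the output *using training rows only*. Two-class outputs are encoded
0/1 for the correlation; with more classes each descriptor scores its
maximum one-vs-rest |r| (an extension beyond the two-class setting the
selector is usually paired with). Zero-variance columns correlate 0 with a
warning. **Double cross-validation** is provided for comparison; its inner
loop may choose different α at different outer folds for the same n, mixing
model complexities — the documented reason to prefer the single-loop grid.

## Complexity ordering and tie-breaks

Every grid point carries an integer complexity rank: k-NN complexity falls
with k, ridge complexity falls with λ, PLS complexity rises with the number
of components, and more selected variables or a larger SVM cost C means more
complex. On the 2-D (n, α) grid the order is lexicographic — fewer variables
first, then the α ranking — because the variable count is the dominant
simplicity axis. Ties in mean loss are exact-equality ties; the winner is
the tied point with the lowest rank. In double CV, step-1 ties across
variable counts go to the smaller count.

## Stratification

Assessment folds are stratified so each fold carries each stratum's
proportion to within one sample: within every stratum the members are
shuffled and dealt round-robin, with the dealing position carried across
strata to keep total fold sizes balanced. Classification strata are the
class labels. For numeric outputs the strata are quantile bins of
consecutive order statistics, ties broken by stable sample order, with
`n_strata = min(V, 5)` by default — a binning rule chosen to guarantee the
proportionality bound while mirroring common practice; a constant output
collapses to one stratum with a warning. Selection folds are deliberately
unstratified: with many repeats, stratification adds little to selection,
while for assessment it keeps every outer fold representative.

## Loss convention

Both losses are per-sample means: mean squared residual for regression and
proportion misclassified for classification. Pooling predictions over all
of D before computing the loss makes the per-repeat value independent of
how samples are distributed over folds, and the mean convention makes plain
and nested CV losses comparable across differing N. (Summed squared
residuals would scale with N and make none of these comparisons
meaningful.)

## Learners and the λ path

Closed-form ridge, NIPALS PLS and k-NN are implemented in the package so
the protocols run self-contained and deterministically; ridge-penalised
logistic regression and the linear SVM delegate to scikit-learn behind the
same builder contract. Every builder standardises descriptors using the
training rows it is given — the leakage rule extended to scaling. The ridge
penalty is ‖y − β₀ − Zβ‖² + λ·N·‖β‖² on standardised Z (logistic maps to
scikit-learn's C = 1/(λN)); the convention is stated here because only the
grid and the fits need to share it.

The λ grid is log-spaced and descending from a data-derived anchor
λ_max = max_j |⟨z_j, y_c⟩| / N — the smallest penalty at which a
soft-thresholding (lasso-type) fit has all-zero slopes, the conventional
path anchor — down to λ_max · min_ratio, with `n_lambda = 100` and
`min_ratio = 1e-6` as defaults. For standalone selection the path is
computed once from the full dataset and held fixed, so grid points are the
same entities across folds and repeats and per-point averaging is well
defined. Inside nested CV the default is the leak-free mode: a
`grid_factory` recomputes the path from each outer training set, so nothing
about the outer held-out fold shapes the grid. The fixed-grid mode remains
available (pass `grid=` instead of `grid_factory=`) for protocols defined
with an externally fixed grid.

k-NN tie-breaks are deterministic: distance ties resolve to the lower
training-row index (stable argsort), majority-vote ties to the
lexicographically smallest label.

## Seeds and parallelism

All pseudo-randomness derives from one base seed through a tagged
SeedSequence path (`derive_seed`): repeat r of a selection uses
(base, "repeat", r); outer repeat r of a nested run uses (base, "outer", r)
and its fold f's inner protocol (seed, "inner", f); double CV tags its three
stages. Seeds are pre-derived before any work is scheduled, so
repeats and outer folds are embarrassingly parallel (`n_jobs` via joblib)
and results are byte-identical for any worker count.

## Pre-processing

The two screens are unsupervised — they never see the output — which is why
running them once before the CV loop is legitimate, unlike supervised
screening. A column is near-zero-variance when its most-common /
second-most-common frequency ratio exceeds 95/5 = 19 **and** its percentage
of distinct values is below 10 (the convention that reproduces standard
descriptor-count bookkeeping; an `any` mode is exposed). Constant columns
are always removed. The linear-combination filter then greedily removes
columns whose residual after projection onto the span of kept lower-indexed
columns is below `tol` (relative), leaving a full-column-rank matrix;
`tol` defaults to max(N, P)·machine-epsilon, which detects exact
dependencies. Real exported data rounds coordinates, so exact dependencies
in the source may no longer be exact in a CSV; `tol` is therefore a config
knob, and the sensitivity of removal counts to export precision should be
checked per dataset rather than assumed.

## Synthetic data

The generators emulate the structure of descriptor tables with a known
answer. Regression: X is iid standard normal, y = Xβ + ε with exactly
`n_informative` leading coefficients of magnitude `coefficient_scale` and
ε ~ N(0, noise_sd²), so Var(y) = n_informative·scale² + noise² is checkable
analytically. Classification: labels are Bernoulli draws from a logistic
model on the informative columns; the intercept controls class balance, a
single-class draw is retried with derived seeds, and a minority fraction
below 5% warns. Decoy blocks append columns engineered to fail each filter
exactly (two-valued columns beyond both near-zero-variance thresholds for
N > 20, constant for smaller N; exact weighted sums of two existing
columns), with indices recorded as ground truth.

What the generators do **not** emulate: correlated descriptor blocks,
heavy-tailed or discrete descriptor distributions (fingerprint sparsity),
label noise, and covariate shift. Passing tests therefore demonstrate that
the protocols are implemented correctly and behave as designed under clean
conditions — not that any particular learner will perform well on real
descriptor sets.

## Problem sizes used in the checks

The default test and acceptance runs use deliberately modest protocol sizes
chosen as good-practice desk-scale settings: tiny N ≤ 20 fixtures for the
exact oracle comparisons; 300 × 50 with 5 informative variables (noise
SD 1) for the recovery and calibration studies; V = 5–10, Nexp = 1–10,
Nexp2 = 5–10 with 10–20 λ values for the repeated runs; and a 20 000-sample
holdout for the calibration reference. A production analysis would
typically use denser grids and more repeats (e.g. V1 = V2 = 10,
Nexp1 = Nexp2 = 50, 100 λ values); nothing in the implementation depends on
the scale.

## Known limitations

- The one-standard-error rule is intentionally absent: with repeated CV the
  standard error shrinks with the number of repeats and the classical rule
  loses its effect; no redefined variant is established.
- Bias-corrected alternatives to nested CV (corrected/penalised CV,
  analytic corrections) are out of scope.
- Only the linear SVM kernel is wired; grouped/blocked splitting (e.g. by
  chemical scaffold) is not implemented.
- Multiclass Pearson selection (one-vs-rest max |r|) is an extension
  without an external convention to match.
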