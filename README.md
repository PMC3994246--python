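# cvprotocols

Repeated and nested cross-validation protocols for selecting and assessing
regression and classification models — built for QSAR-style problems
(predicting a compound's activity from numeric molecular descriptors), and
usable on any tabular dataset with one output column.

## Why

Two pitfalls dominate practical cross-validation:

1. **Selection on a single CV run.** Different pseudo-random V-fold splits
   pick different "optimal" tuning parameters; the winner of one split is a
   noisy draw from a distribution, not the answer.
2. **Reporting the winner's own CV loss as its error estimate.** The
   resampling that picked the winner also scored it, so the reported loss is
   optimistic — and selecting variables *before* cross-validation instead of
   inside it biases the estimate further.

`cvprotocols` implements the protocols that avoid both:

- **Repeated grid-search CV** for parameter tuning: run `Nexp` independent
  V-fold cross-validations over a grid α₁…α_K; choose the α minimising the
  *mean* CV loss, ties broken toward the simpler model (larger k or λ, fewer
  components or variables).
- **Repeated stratified nested CV** for assessment: in each of `Nexp2` outer
  repeats, stratify the output, split into V2 folds, rerun the *entire*
  selection protocol on every outer training set, and score the chosen model
  only on its held-out fold. The mean of the nested errors is the
  **P-estimate** of the large-sample error of the model chosen by protocol P;
  their min–max range is the **P-estimated interval**. Both describe the
  (model, protocol) pair, not the model alone.
- **Variable selection inside CV**: a 2-D grid over (number of variables n,
  tuning parameter α), with the per-fold variable ranking (|Pearson r|)
  computed from training rows only.
- **Double cross-validation** (Stone): outer CV over variable counts with an
  internal CV choosing α per fold, then a final CV for α on the chosen subset.

Supporting machinery: unsupervised descriptor screens (near-zero-variance
with the 95/5 = 19 frequency-ratio and 10% distinct-value thresholds; exact
linear-combination removal), stratified and unstratified fold generation,
self-contained reference learners (closed-form ridge, NIPALS PLS, k-NN) plus
scikit-learn-backed logistic ridge and linear SVM, and synthetic-data
generators with full ground-truth bookkeeping.

Losses are per-sample means (mean squared residual; proportion
misclassified), so values pool exactly across folds and are comparable
across dataset sizes. Every run is a pure function of its base seed,
independent of worker count.

## Worked example

```python
from cvprotocols import (
    CVProtocol, NestedCVConfig, RidgeBuilder, SyntheticSpec,
    generate_regression, optimism_report, ridge_lambda_grid,
    squared_error_cv_loss,
)

ds, _ = generate_regression(
    SyntheticSpec(n_samples=200, n_variables=30, n_informative=5,
                  coefficient_scale=1.0, noise_sd=1.0, seed=3))
grid = ridge_lambda_grid(ds, n_lambda=20)
protocol = CVProtocol(grid=grid, V=5, Nexp=5, loss=squared_error_cv_loss,
                      builder=RidgeBuilder(), base_seed=42)
config = NestedCVConfig(
    builder=RidgeBuilder(), loss=squared_error_cv_loss,
    V1=5, Nexp1=2, V2=5, Nexp2=10,
    grid_factory=lambda d: ridge_lambda_grid(d, n_lambda=20),
    base_seed=42)
report = optimism_report(ds, protocol, config)
print(f"CV loss of the chosen model:   {report.cv_loss_chosen:.4f}")
print(f"P-estimate (nested CV mean):   {report.p_estimate:.4f}")
print(f"P-estimated interval:          [{report.nested.interval[0]:.4f}, "
      f"{report.nested.interval[1]:.4f}]")
print(f"optimism (CV - P-estimate):    {report.optimism:+.4f}")
```

prints

```
CV loss of the chosen model:   1.4682
P-estimate (nested CV mean):   1.4894
P-estimated interval:          [1.3726, 1.5838]
optimism (CV - P-estimate):    -0.0213
```

The data carry unit-variance noise, so a perfect model would score ≈ 1.0;
the chosen ridge model's CV loss (1.468) understates its nested assessment
(1.489) by 0.021 — the selection optimism — and a single nested run could
have returned anything from 1.37 to 1.58, which is why the interval is
reported rather than one number. More narrative walkthroughs live in
`examples/` (one script per capability), and a thin CLI is available:
`cvprot simulate | preprocess | select | assess | report`.

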