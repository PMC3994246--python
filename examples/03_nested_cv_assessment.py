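"""Assessing the selected model with repeated stratified nested CV.

The cross-validation loss of the winning grid point is an optimistic
estimate of its error (the same resampling picked the winner and scored it).
Nested cross-validation reruns the whole selection inside every outer fold
and reports the P-estimate and P-estimated interval instead.
"""

from cvprotocols import (
    CVProtocol, NestedCVConfig, RidgeBuilder, SyntheticSpec,
    generate_regression, optimism_report, ridge_lambda_grid,
    squared_error_cv_loss,
)

ds, _ = generate_regression(
    SyntheticSpec(n_samples=200, n_variables=30, n_informative=5,
                  coefficient_scale=1.0, noise_sd=1.0, seed=3)
)
grid = ridge_lambda_grid(ds, n_lambda=20)
protocol = CVProtocol(grid=grid, V=5, Nexp=5, loss=squared_error_cv_loss,
                      builder=RidgeBuilder(), base_seed=42)
config = NestedCVConfig(
    builder=RidgeBuilder(), loss=squared_error_cv_loss,
    V1=5, Nexp1=2, V2=5, Nexp2=10,
    grid_factory=lambda d: ridge_lambda_grid(d, n_lambda=20),  # leak-free path
    base_seed=42,
)
report = optimism_report(ds, protocol, config)

print(f"CV loss of the chosen model:   {report.cv_loss_chosen:.4f}")
print(f"P-estimate (nested CV mean):   {report.p_estimate:.4f}")
print(f"P-estimated interval:          [{report.nested.interval[0]:.4f}, "
      f"{report.nested.interval[1]:.4f}]")
print(f"optimism (CV - P-estimate):    {report.optimism:+.4f}")
# A negative optimism means the selection CV loss understates the error the
# chosen model would make on new data; the interval shows how much a single
# nested run can vary with the outer partition.  Both numbers describe the
# (model, protocol) pair, not the model alone.
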