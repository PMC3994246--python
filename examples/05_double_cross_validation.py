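"""Stone's double cross-validation, side by side with the 2-D grid search.

Double CV picks the variable count in an outer loop while an internal CV
chooses the tuning parameter per (fold, count).  Because different outer
folds may pick different tuning parameters at the same count, it can average
over models of different complexity — the reason the single-loop 2-D grid
search is generally preferred when both knobs affect complexity.
"""

from cvprotocols import (
    CVProtocol, PearsonSelector, RidgeBuilder, SyntheticSpec,
    double_cross_validation, generate_regression, make_selection_grid,
    repeated_grid_search_cv_with_selection, ridge_lambda_grid,
    squared_error_cv_loss,
)

ds, truth = generate_regression(
    SyntheticSpec(n_samples=150, n_variables=20, n_informative=4,
                  coefficient_scale=1.5, noise_sd=1.0, seed=21)
)
lam_grid = ridge_lambda_grid(ds, n_lambda=8)
n_values = [2, 4, 8, 16, 20]

dcv = double_cross_validation(ds, PearsonSelector(), RidgeBuilder(), lam_grid,
                              n_values=n_values, V1=5, V2=5,
                              loss=squared_error_cv_loss, base_seed=9)
print(f"double CV:   chose n = {dcv.p_chosen}, {dcv.alpha_chosen.label}")
print(f"  step-1 losses per n: "
      f"{ {n: round(v, 3) for n, v in dcv.step1_losses.items()} }")

protocol = CVProtocol(grid=make_selection_grid(n_values, lam_grid),
                      V=5, Nexp=3, loss=squared_error_cv_loss,
                      builder=RidgeBuilder(), selector=PearsonSelector(),
                      base_seed=9)
gs = repeated_grid_search_cv_with_selection(ds, protocol)
print(f"grid search: chose n = {gs.chosen['n_variables']}, "
      f"lambda={gs.chosen['lambda']:.4g} "
      f"(mean loss {gs.best_mean_loss:.3f})")
print(f"informative columns: {truth.informative_idx}")
# The two procedures may legitimately disagree on n; on clean sparse-signal
# data both should land near the true number of informative variables.
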