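"""Model assessment by repeated stratified nested cross-validation.

A cross-validation error of a cross-validatory *chosen* model is optimistic:
the same resampling that picked the winner also scored it.  Nested
cross-validation removes that selection bias by rerunning the entire
selection protocol inside every outer training set and scoring the chosen
model only on the outer held-out fold.  Because a single nested run still
varies substantially with the outer partition, the procedure is repeated:
the mean of the Nexp2 nested errors is the **P-estimate** of the large-sample
error of the model chosen by protocol P, and the min–max range of those
errors is the **P-estimated interval**.  Both are properties of the
(model, protocol) pair — two protocols scanning different grids yield two
different, equally valid, P-estimates.

Outer folds are stratified on the output (class labels, or quantile bins of
a numeric output); the inner selection loop stays unstratified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .data_model import REGRESSION, Dataset
from .partitioning import make_stratified_folds
from .selection import CVProtocol, repeated_grid_search_cv

__all__ = [
    "NestedCVConfig", "NestedCVResult", "single_nested_cv",
    "repeated_nested_cv", "optimism_report", "OptimismReport",
    "summarize_repeats",
]


@dataclass
class NestedCVConfig:
    """Inner selection protocol plus the outer assessment loop.

    ``grid`` is the fixed inner grid; alternatively ``grid_factory`` (a
    callable dataset → grid) recomputes a data-derived grid (e.g. a ridge λ
    path) from each outer training set, so nothing about the held-out fold
    leaks into the grid — the leak-free mode, and the default whenever a
    factory is supplied.
    """

    builder: object
    loss: "callable"
    V1: int
    Nexp1: int
    V2: int
    Nexp2: int
    grid: tuple | None = None
    grid_factory: object | None = None
    selector: object | None = None
    n_strata: int | None = None
    base_seed: int = 0

    def __post_init__(self):
        if self.V1 < 2 or self.V2 < 2:
            raise ValueError("V1 and V2 must be >= 2")
        if self.Nexp1 < 1 or self.Nexp2 < 1:
            raise ValueError("Nexp1 and Nexp2 must be >= 1")
        if (self.grid is None) == (self.grid_factory is None):
            raise ValueError("provide exactly one of grid / grid_factory")

    def inner_grid(self, train: Dataset) -> tuple:
        return self.grid if self.grid is not None else tuple(self.grid_factory(train))

    @property
    def identifier(self) -> str:
        g = "factory" if self.grid_factory is not None else f"K={len(self.grid)}"
        sel = type(self.selector).__name__ if self.selector else "none"
        return (
            f"nested[{type(self.builder).__name__}|{g}|V1={self.V1}"
            f"|Nexp1={self.Nexp1}|V2={self.V2}|Nexp2={self.Nexp2}"
            f"|selector={sel}|seed={self.base_seed}]"
        )


@dataclass
class NestedCVResult:
    """Nexp2 nested CV errors with their mean and min–max interval."""

    errors: np.ndarray
    p_estimate: float
    interval: tuple[float, float]
    fold_choices: list          # per repeat: list of (outer fold, chosen ParamPoint)
    protocol_id: str

    def summary(self) -> dict:
        return {
            "protocol": self.protocol_id,
            "p_estimate": self.p_estimate,
            "interval_min": self.interval[0],
            "interval_max": self.interval[1],
            "n_repeats": int(len(self.errors)),
        }


def single_nested_cv(
    dataset: Dataset, config: NestedCVConfig, seed: int
) -> tuple[float, list]:
    """One nested cross-validation error (plus the per-fold audit trail).

    The output is stratified and split into V2 outer folds.  For every outer
    fold, the full selection protocol — Nexp1-repeated V1-fold grid-search
    CV, with variable selection inside if configured — runs on the training
    complement L alone; the chosen model (refit on L) predicts the held-out
    fold.  The nested CV error is the loss pooled over all of D.
    """
    folds = make_stratified_folds(
        dataset.y, dataset.task, config.V2, seed, n_strata=config.n_strata
    )
    if dataset.task == REGRESSION:
        preds = np.full(dataset.n_samples, np.nan)
    else:
        preds = np.empty(dataset.n_samples, dtype=object)
    audit = []
    for f, train_idx, test_idx in folds.iter_folds():
        L = dataset.subset_rows(train_idx)
        protocol = CVProtocol(
            grid=config.inner_grid(L),
            V=config.V1,
            Nexp=config.Nexp1,
            loss=config.loss,
            builder=config.builder,
            selector=config.selector,
            base_seed=derive_seed(seed, "inner", f),
        )
        res = repeated_grid_search_cv(L, protocol)
        Xt = dataset.X[test_idx]
        if res.chosen_columns is not None:
            Xt = Xt[:, res.chosen_columns]
        preds[test_idx] = res.final_model.predict(Xt)
        audit.append((f, res.chosen))
    return float(config.loss(dataset.y, preds)), audit


def repeated_nested_cv(
    dataset: Dataset, config: NestedCVConfig, n_jobs: int = 1
) -> NestedCVResult:
    """Nexp2 nested cross-validations with independent outer partitions.

    Each repeat re-stratifies and re-partitions the outer loop under a seed
    derived from the config's base seed, so the whole result is a pure
    function of (dataset, config, base_seed) for any worker count.
    """
    seeds = [derive_seed(config.base_seed, "outer", r) for r in range(config.Nexp2)]
    if n_jobs != 1:
        from joblib import Parallel, delayed

        pairs = Parallel(n_jobs=n_jobs)(
            delayed(single_nested_cv)(dataset, config, s) for s in seeds
        )
    else:
        pairs = [single_nested_cv(dataset, config, s) for s in seeds]
    errors = np.asarray([e for e, _ in pairs])
    return NestedCVResult(
        errors=errors,
        p_estimate=float(errors.mean()),
        interval=(float(errors.min()), float(errors.max())),
        fold_choices=[a for _, a in pairs],
        protocol_id=config.identifier,
    )


@dataclass
class OptimismReport:
    """Paired selection CV loss and nested P-estimate."""

    cv_loss_chosen: float
    p_estimate: float
    optimism: float             # cv_loss_chosen - p_estimate; typically <= 0
    selection: object
    nested: NestedCVResult


def optimism_report(
    dataset: Dataset, protocol: CVProtocol, config: NestedCVConfig, n_jobs: int = 1
) -> OptimismReport:
    """How optimistic is the chosen model's own CV loss?

    Runs the selection protocol and the nested assessment from the same base
    seed lineage and reports (chosen-model mean CV loss, P-estimate, their
    difference).  A negative difference is the selection bias nested CV
    exists to expose; with a single-point grid there is no selection and the
    difference reflects only partition/stratification noise.
    """
    sel = repeated_grid_search_cv(dataset, protocol, n_jobs=n_jobs)
    nested = repeated_nested_cv(dataset, config, n_jobs=n_jobs)
    cv_loss = sel.best_mean_loss
    return OptimismReport(
        cv_loss_chosen=cv_loss,
        p_estimate=nested.p_estimate,
        optimism=cv_loss - nested.p_estimate,
        selection=sel,
        nested=nested,
    )


def summarize_repeats(loss_table: np.ndarray, grid: tuple | None = None) -> pd.DataFrame:
    """Five-number summary (min, Q1, median, Q3, max) of per-repeat losses.

    One row per grid point, over the Nexp repeats.  Quartiles use linear
    interpolation between order statistics (numpy's default convention).
    """
    loss_table = np.atleast_2d(np.asarray(loss_table, dtype=float))
    if loss_table.shape[0] < 1:
        raise ValueError("need at least one repeat")
    qs = np.percentile(loss_table, [0, 25, 50, 75, 100], axis=0)
    index = [pt.label for pt in grid] if grid is not None else list(range(loss_table.shape[1]))
    return pd.DataFrame(
        {"min": qs[0], "q1": qs[1], "median": qs[2], "q3": qs[3], "max": qs[4]},
        index=index,
    )
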