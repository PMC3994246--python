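"""Model selection by repeated grid-search cross-validation.

Three selection procedures share one engine:

* repeated grid-search CV for parameter tuning — Nexp independent V-fold
  reshuffles; the grid point with the lowest *mean* CV loss is the optimal
  cross-validatory choice, ties broken toward the lower complexity rank;
* the same with variable selection *inside* the loop — a 2-D grid over
  (number of selected variables n, tuning parameter α), where the selector
  sees only the training complement of each fold, never the held-out fold,
  so no information leaks from the assessment rows into the variable ranking;
* Stone's double cross-validation — an outer loop over variable counts with
  an internal CV choosing α per (fold, count), then a final CV for α on the
  chosen variable subset.

Selection folds are deliberately unstratified; stratification is reserved
for assessment (see :mod:`cvprotocols.assessment`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .data_model import CLASSIFICATION, REGRESSION, Dataset
from .learners import ParamPoint
from .partitioning import make_folds

__all__ = [
    "CVProtocol", "SelectionResult", "ProtocolError",
    "PearsonSelector", "pearson_rank_select",
    "single_cv_losses", "repeated_grid_search_cv",
    "repeated_grid_search_cv_with_selection",
    "optimal_param_distribution", "make_selection_grid",
    "double_cross_validation", "DoubleCVResult",
]


class ProtocolError(RuntimeError):
    """A grid point could not be evaluated under the protocol."""


@dataclass
class CVProtocol:
    """The cross-validation protocol: grid, folds, repeats, loss, builder.

    Two runs with the same protocol and base seed produce identical results;
    an assessment is a statement about (model, protocol), so the protocol
    identity travels with every result.
    """

    grid: tuple
    V: int
    Nexp: int
    loss: "callable"
    builder: object
    selector: object | None = None
    base_seed: int = 0

    def __post_init__(self):
        self.grid = tuple(self.grid)
        if len(self.grid) < 1:
            raise ValueError("grid must contain at least one point")
        if self.Nexp < 1:
            raise ValueError("Nexp must be >= 1")
        ranks = [pt.complexity_rank for pt in self.grid]
        if len(set(ranks)) != len(ranks):
            raise ValueError("complexity ranks must totally order the grid")

    @property
    def identifier(self) -> str:
        sel = type(self.selector).__name__ if self.selector else "none"
        return (
            f"{type(self.builder).__name__}|K={len(self.grid)}|V={self.V}"
            f"|Nexp={self.Nexp}|selector={sel}|seed={self.base_seed}"
        )


@dataclass
class SelectionResult:
    """Outcome of a repeated grid-search cross-validation."""

    loss_table: np.ndarray          # Nexp × K per-repeat CV losses
    mean_loss: np.ndarray           # K column means
    per_repeat_argmin: list         # ParamPoint chosen by each single CV
    chosen: ParamPoint              # optimal cross-validatory choice
    chosen_index: int
    final_model: object
    grid: tuple
    protocol_id: str
    chosen_columns: np.ndarray | None = None
    selection_audit: dict = field(default_factory=dict)

    @property
    def best_mean_loss(self) -> float:
        return float(self.mean_loss[self.chosen_index])

    def summary(self) -> dict:
        d = {
            "protocol": self.protocol_id,
            "lowest_mean_cv_loss": self.best_mean_loss,
            "chosen": self.chosen.label,
            "grid_size": len(self.grid),
        }
        if self.chosen_columns is not None:
            d["n_selected_variables"] = int(len(self.chosen_columns))
        return d


# --------------------------------------------------------------------------
# Pearson's rank-based variable selection

def pearson_rank_select(train: Dataset, p: int) -> np.ndarray:
    """Indices of the p descriptors with largest |Pearson correlation| to y.

    Correlations are ranked by absolute value, descending, ties broken by
    ascending column index.  Classification outputs are encoded 0/1 for two
    classes; with more classes each variable scores its maximum one-vs-rest
    |r|.  A zero-variance column correlates 0 (with a warning), never errors.
    """
    P = train.n_variables
    if not (1 <= p <= P):
        raise ValueError(f"p = {p} out of range [1, {P}]")
    if train.n_samples < 3:
        raise ValueError("need at least 3 rows for correlation ranking")
    X = train.X
    if train.task == REGRESSION:
        targets = [np.asarray(train.y, dtype=float)]
    else:
        classes = train.classes
        if len(classes) == 2:
            targets = [np.asarray([classes.index(v) for v in train.y], dtype=float)]
        else:
            targets = [
                np.asarray([1.0 if v == c else 0.0 for v in train.y]) for c in classes
            ]
    abs_r = np.zeros(P)
    warned = False
    for yv in targets:
        yc = yv - yv.mean()
        ynorm = np.linalg.norm(yc)
        Xc = X - X.mean(axis=0)
        xnorm = np.linalg.norm(Xc, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc.T @ yc) / (xnorm * ynorm)
        bad = (xnorm == 0) | (ynorm == 0)
        if bad.any() and not warned:
            warnings.warn("zero-variance column(s): correlation taken as 0", stacklevel=2)
            warned = True
        r[~np.isfinite(r)] = 0.0
        abs_r = np.maximum(abs_r, np.abs(r))
    order = sorted(range(P), key=lambda j: (-abs_r[j], j))
    return np.asarray(order[:p], dtype=int)


class PearsonSelector:
    """VariableSelector wrapping :func:`pearson_rank_select`."""

    def select(self, train: Dataset, p: int) -> np.ndarray:
        return pearson_rank_select(train, p)


# --------------------------------------------------------------------------
# the single-repeat engine

def _empty_preds(dataset: Dataset, k: int):
    if dataset.task == REGRESSION:
        return np.full((k, dataset.n_samples), np.nan)
    return np.empty((k, dataset.n_samples), dtype=object)


def _fit_predict(builder, point, train, Xtest, fold):
    try:
        model = builder.fit(train, point)
        return model.predict(Xtest)
    except ProtocolError:
        raise
    except Exception as exc:
        raise ProtocolError(
            f"grid point ({point.label}) unfittable on fold {fold}: {exc}"
        ) from exc


def single_cv_losses(
    dataset: Dataset,
    protocol: CVProtocol,
    seed: int,
    audit: dict | None = None,
) -> np.ndarray:
    """One V-fold cross-validation pass: a loss per grid point.

    Every grid point is fit on each training complement L and applied to the
    held-out fold T; predictions are pooled over all of D before the loss is
    computed, so the result is the per-sample mean loss over the whole
    dataset.  With a selector, variables are chosen per fold from L only and
    the audit dict (if given) records {(fold, n): column indices}.
    """
    K = len(protocol.grid)
    preds = _empty_preds(dataset, K)
    folds = make_folds(dataset.n_samples, protocol.V, seed)
    for f, train_idx, test_idx in folds.iter_folds():
        L = dataset.subset_rows(train_idx)
        Xtest = dataset.X[test_idx]
        if protocol.selector is None:
            for k, pt in enumerate(protocol.grid):
                preds[k, test_idx] = _fit_predict(protocol.builder, pt, L, Xtest, f)
        else:
            n_values = sorted({pt["n_variables"] for pt in protocol.grid})
            for n in n_values:
                cols = np.asarray(protocol.selector.select(L, n), dtype=int)
                if audit is not None:
                    audit[(f, n)] = cols
                Ln = L.subset_columns(cols)
                Xt = Xtest[:, cols]
                for k, pt in enumerate(protocol.grid):
                    if pt["n_variables"] != n:
                        continue
                    preds[k, test_idx] = _fit_predict(protocol.builder, pt, Ln, Xt, f)
    return np.asarray([protocol.loss(dataset.y, preds[k]) for k in range(K)])


def choose_best(mean_loss: np.ndarray, grid: tuple) -> int:
    """Index of the minimal mean loss; exact ties go to the lowest
    complexity rank."""
    best = np.min(mean_loss)
    tied = [k for k in range(len(grid)) if mean_loss[k] == best]
    return min(tied, key=lambda k: grid[k].complexity_rank)


def repeated_grid_search_cv(
    dataset: Dataset, protocol: CVProtocol, n_jobs: int = 1
) -> SelectionResult:
    """Repeated grid-search cross-validation (parameter tuning).

    Runs ``Nexp`` single cross-validations with per-repeat reshuffled folds
    (repeat r's seed is derived from the protocol base seed, so the result
    is identical for any worker count), averages the losses per grid point,
    and picks the point with minimal mean loss — ties toward the simpler
    model.  The final model is refit on all of D at the chosen point.
    """
    seeds = [derive_seed(protocol.base_seed, "repeat", r) for r in range(protocol.Nexp)]
    audits = [dict() for _ in seeds] if protocol.selector else [None] * len(seeds)
    if n_jobs != 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(
            delayed(single_cv_losses)(dataset, protocol, s, a)
            for s, a in zip(seeds, audits)
        )
    else:
        rows = [single_cv_losses(dataset, protocol, s, a) for s, a in zip(seeds, audits)]
    loss_table = np.vstack(rows)
    mean_loss = loss_table.mean(axis=0)
    chosen_idx = choose_best(mean_loss, protocol.grid)
    chosen = protocol.grid[chosen_idx]
    per_repeat = [
        protocol.grid[choose_best(loss_table[r], protocol.grid)]
        for r in range(protocol.Nexp)
    ]
    chosen_columns = None
    if protocol.selector is not None:
        chosen_columns = np.asarray(
            protocol.selector.select(dataset, chosen["n_variables"]), dtype=int
        )
        final_model = protocol.builder.fit(dataset.subset_columns(chosen_columns), chosen)
    else:
        final_model = protocol.builder.fit(dataset, chosen)
    audit = {}
    if protocol.selector is not None:
        for r, a in enumerate(audits):
            for (f, n), cols in a.items():
                audit[(r, f, n)] = cols
    return SelectionResult(
        loss_table=loss_table,
        mean_loss=mean_loss,
        per_repeat_argmin=per_repeat,
        chosen=chosen,
        chosen_index=chosen_idx,
        final_model=final_model,
        grid=protocol.grid,
        protocol_id=protocol.identifier,
        chosen_columns=chosen_columns,
        selection_audit=audit,
    )


def repeated_grid_search_cv_with_selection(
    dataset: Dataset, protocol: CVProtocol, n_jobs: int = 1
) -> SelectionResult:
    """Variable selection + tuning on a 2-D (n, α) grid inside repeated CV.

    Identical engine to :func:`repeated_grid_search_cv` but requires a
    selector and a grid carrying ``n_variables``; within every fold the
    selector is applied to the training complement only.
    """
    if protocol.selector is None:
        raise ValueError("protocol must carry a variable selector")
    for pt in protocol.grid:
        if pt.get("n_variables") is None:
            raise ValueError("every grid point needs an 'n_variables' entry")
    return repeated_grid_search_cv(dataset, protocol, n_jobs=n_jobs)


def make_selection_grid(n_values, alpha_grid) -> tuple:
    """2-D grid over (n_variables, α) with lexicographic complexity.

    Complexity orders by (n_variables ascending, then the α grid's own
    complexity rank), so the fewest-variables simplest-α point is the
    simplest overall — the tie-break axis that matters most.
    """
    n_values = sorted(set(int(n) for n in n_values))
    alphas = sorted(alpha_grid, key=lambda pt: pt.complexity_rank)
    out = []
    rank = 0
    for n in n_values:
        for a in alphas:
            out.append(a.with_param(rank, n_variables=n))
            rank += 1
    return tuple(out)


def optimal_param_distribution(result: SelectionResult) -> pd.Series:
    """Frequency table of the per-repeat optimal grid points.

    Each single cross-validation repeat contributes the argmin of its own
    loss row (same lowest-complexity tie-break as the mean-based choice);
    counts sum to Nexp.  The spread of this distribution is the variance a
    single unrepeated cross-validation would silently inherit.
    """
    labels = [pt.label for pt in result.grid]
    counts = {lab: 0 for lab in labels}
    for pt in result.per_repeat_argmin:
        counts[pt.label] += 1
    s = pd.Series(counts, name="frequency")
    return s[s > 0]


# --------------------------------------------------------------------------
# double cross-validation

@dataclass
class DoubleCVResult:
    p_chosen: int
    alpha_chosen: ParamPoint
    final_model: object
    selected_columns: np.ndarray
    step1_losses: dict          # n -> pooled loss over D
    step2_losses: np.ndarray    # per-α loss in the final tuning CV
    inner_alpha_audit: dict     # (outer fold, n) -> α chosen internally


def double_cross_validation(
    dataset: Dataset,
    selector,
    builder,
    alpha_grid,
    n_values,
    V1: int,
    V2: int,
    loss,
    base_seed: int = 0,
) -> DoubleCVResult:
    """Stone-style double cross-validation for variable count and tuning.

    Step 1 — an outer V1-fold loop scores each candidate variable count p:
    within every outer training set L, the selector picks p variables, an
    internal V2-fold CV over the α grid (on L alone) picks α for this
    (fold, p), the model is refit on the reduced L and applied to the
    held-out fold; p′ minimises the loss pooled over D.  Step 2 — with D
    reduced to its p′ selected variables, a fresh V1-fold CV picks α′, and
    the final model is fit on the reduced D at α′.

    Unlike the 2-D grid search, the internal loop may pick different α for
    different outer folds at the same p, averaging over models of different
    complexity — the reason grid search is generally preferred.
    """
    alpha_grid = tuple(alpha_grid)
    n_values = sorted(set(int(n) for n in n_values))
    N = dataset.n_samples
    outer = make_folds(N, V1, derive_seed(base_seed, "dcv", 0))
    preds = {
        n: _empty_preds(dataset, 1)[0] for n in n_values
    }
    inner_audit = {}
    for f, train_idx, test_idx in outer.iter_folds():
        L = dataset.subset_rows(train_idx)
        for pi, p in enumerate(n_values):
            cols = np.asarray(selector.select(L, p), dtype=int)
            Lp = L.subset_columns(cols)
            inner = make_folds(Lp.n_samples, V2, derive_seed(base_seed, "dcv", 1, f, pi))
            ipreds = _empty_preds(Lp, len(alpha_grid))
            for g, itr, ite in inner.iter_folds():
                LL = Lp.subset_rows(itr)
                Xt = Lp.X[ite]
                for k, pt in enumerate(alpha_grid):
                    ipreds[k, ite] = _fit_predict(builder, pt, LL, Xt, (f, g))
            ilosses = np.asarray([loss(Lp.y, ipreds[k]) for k in range(len(alpha_grid))])
            a_idx = choose_best(ilosses, alpha_grid)
            inner_audit[(f, p)] = alpha_grid[a_idx]
            model = builder.fit(Lp, alpha_grid[a_idx])
            preds[p][test_idx] = model.predict(dataset.X[np.ix_(test_idx, cols)])
    step1 = {n: float(loss(dataset.y, preds[n])) for n in n_values}
    best = min(step1.values())
    p_chosen = min(n for n, v in step1.items() if v == best)  # ties -> fewer variables

    cols = np.asarray(selector.select(dataset, p_chosen), dtype=int)
    Dp = dataset.subset_columns(cols)
    folds2 = make_folds(N, V1, derive_seed(base_seed, "dcv", 2))
    fpreds = _empty_preds(Dp, len(alpha_grid))
    for f, train_idx, test_idx in folds2.iter_folds():
        L = Dp.subset_rows(train_idx)
        Xt = Dp.X[test_idx]
        for k, pt in enumerate(alpha_grid):
            fpreds[k, test_idx] = _fit_predict(builder, pt, L, Xt, f)
    step2 = np.asarray([loss(Dp.y, fpreds[k]) for k in range(len(alpha_grid))])
    a_idx = choose_best(step2, alpha_grid)
    alpha_chosen = alpha_grid[a_idx]
    final_model = builder.fit(Dp, alpha_chosen)
    return DoubleCVResult(
        p_chosen=p_chosen,
        alpha_chosen=alpha_chosen,
        final_model=final_model,
        selected_columns=cols,
        step1_losses=step1,
        step2_losses=step2,
        inner_alpha_audit=inner_audit,
    )
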