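"""Unsupervised descriptor screens run once before any cross-validation.

Two filters, applied in a fixed order: near-zero-variance removal (columns
dominated by a single value, or with too few distinct values, cannot support
resampling) followed by exact linear-combination removal (columns carrying no
information beyond the others in this sample).  Both are unsupervised — they
never look at the output variable — which is what makes running them outside
the cross-validation loop legitimate, in contrast to supervised screening.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .data_model import Dataset, DatasetError

__all__ = [
    "FilterReport",
    "near_zero_variance_filter",
    "linear_combination_filter",
    "preprocess",
]

FREQ_RATIO_CUT = 19.0  # 95/5
UNIQUE_PCT_CUT = 10.0


@dataclass
class FilterReport:
    """Which columns each filter removed, and with what thresholds.

    ``removed_nzv``, ``removed_lincomb`` and ``kept`` partition the original
    column indices; the linear-combination filter always runs second.
    """

    removed_nzv: list[int]
    removed_lincomb: list[int]
    kept: list[int]
    freq_ratio_cut: float = FREQ_RATIO_CUT
    unique_pct_cut: float = UNIQUE_PCT_CUT
    mode: str = "both"
    lincomb_tol: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FilterReport":
        return cls(**json.loads(text))


def nzv_column_stats(col: np.ndarray) -> tuple[float, float]:
    """(frequency ratio, percent distinct) for one column.

    The frequency ratio divides the largest value count by the second
    largest, regardless of which values attain them; a constant column has
    no second value and gets ratio +inf.
    """
    _, counts = np.unique(col, return_counts=True)
    n = col.size
    pct_unique = 100.0 * counts.size / n
    if counts.size == 1:
        return np.inf, pct_unique
    top2 = np.sort(counts)[-2:]
    return top2[1] / top2[0], pct_unique


def near_zero_variance_filter(
    X: np.ndarray,
    freq_ratio_cut: float = FREQ_RATIO_CUT,
    unique_pct_cut: float = UNIQUE_PCT_CUT,
    mode: str = "both",
) -> list[int]:
    """Indices of near-zero-variance columns.

    A column is flagged when its most-common/second-most-common frequency
    ratio exceeds ``freq_ratio_cut`` (default 95/5 = 19) and/or its percent
    of distinct values falls below ``unique_pct_cut`` (default 10).  With
    ``mode="both"`` both criteria must hold (the convention that reproduces
    the standard descriptor-count bookkeeping); ``mode="any"`` flags on
    either.  A constant column is always flagged.
    """
    if mode not in ("both", "any"):
        raise ValueError(f"mode must be 'both' or 'any', got {mode!r}")
    X = np.asarray(X)
    if X.size == 0:
        raise ValueError("empty descriptor matrix")
    flagged = []
    for j in range(X.shape[1]):
        ratio, pct = nzv_column_stats(X[:, j])
        if np.isinf(ratio):  # constant: no second value
            flagged.append(j)
            continue
        hit_ratio = ratio > freq_ratio_cut
        hit_pct = pct < unique_pct_cut
        hit = (hit_ratio and hit_pct) if mode == "both" else (hit_ratio or hit_pct)
        if hit:
            flagged.append(j)
    return flagged


def linear_combination_filter(X: np.ndarray, tol: float | None = None) -> list[int]:
    """Indices of columns that are linear combinations of lower-indexed ones.

    Greedy left-to-right elimination: a column whose residual after
    projection onto the span of the kept columns is below ``tol`` (relative
    to its own norm) is dropped.  Removing the returned columns leaves a
    full-column-rank matrix; the result is deterministic given column order.
    ``tol`` defaults to max(N, P)·eps, tight enough for exact dependencies;
    raise it when CSV-export rounding has broken exactness.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows for linear-combination detection")
    if tol is None:
        tol = max(n, p) * np.finfo(float).eps
    removed: list[int] = []
    basis: list[np.ndarray] = []  # orthonormal basis of kept columns
    for j in range(p):
        x = X[:, j]
        norm = np.linalg.norm(x)
        if norm == 0:
            removed.append(j)
            continue
        r = x.copy()
        for q in basis:
            r -= (q @ r) * q
        # second Gram-Schmidt pass for numerical stability
        for q in basis:
            r -= (q @ r) * q
        if np.linalg.norm(r) <= tol * norm:
            removed.append(j)
        else:
            basis.append(r / np.linalg.norm(r))
    return removed


def preprocess(
    dataset: Dataset,
    freq_ratio_cut: float = FREQ_RATIO_CUT,
    unique_pct_cut: float = UNIQUE_PCT_CUT,
    mode: str = "both",
    lincomb_tol: float | None = None,
) -> tuple[Dataset, FilterReport]:
    """Near-zero-variance then linear-combination filtering of a dataset.

    Returns the reduced dataset and a report whose removed/kept lists
    partition the original column indices.  Raises if every column would be
    removed.
    """
    nzv = near_zero_variance_filter(dataset.X, freq_ratio_cut, unique_pct_cut, mode)
    survivors = [j for j in range(dataset.n_variables) if j not in set(nzv)]
    if not survivors:
        raise DatasetError("all columns removed by near-zero-variance filter")
    lin_local = linear_combination_filter(dataset.X[:, survivors], tol=lincomb_tol)
    lin = [survivors[j] for j in lin_local]
    kept = [j for j in survivors if j not in set(lin)]
    if not kept:
        raise DatasetError("all columns removed by preprocessing")
    report = FilterReport(
        removed_nzv=nzv,
        removed_lincomb=lin,
        kept=kept,
        freq_ratio_cut=freq_ratio_cut,
        unique_pct_cut=unique_pct_cut,
        mode=mode,
        lincomb_tol=lincomb_tol,
    )
    return dataset.subset_columns(kept), report
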