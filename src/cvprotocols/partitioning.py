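"""Pseudo-random V-fold partitions, with and without output stratification.

Model *selection* uses plain shuffled folds; model *assessment* uses folds
stratified on the output variable so every fold sees the same class (or
output-quantile) mix.  All assignments are deterministic functions of their
inputs and seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import CLASSIFICATION, REGRESSION

__all__ = ["FoldAssignment", "make_folds", "stratify_output", "make_stratified_folds"]


@dataclass
class FoldAssignment:
    """Fold label (1..V) per sample."""

    fold_of: np.ndarray
    V: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)

    def iter_folds(self):
        for f in range(1, self.V + 1):
            yield f, self.train_indices(f), self.test_indices(f)

    def to_json(self) -> str:
        return json.dumps(
            {"fold_of": self.fold_of.tolist(), "V": self.V, "seed": self.seed}
        )


def _check_v(n: int, v: int) -> None:
    if v < 2:
        raise ValueError(f"V must be >= 2, got {v}")
    if v > n:
        raise ValueError(f"V = {v} exceeds number of samples N = {n}")


def make_folds(N: int, V: int, seed: int) -> FoldAssignment:
    """Size-balanced random partition of N samples into V folds.

    Indices are shuffled and dealt cyclically, so fold sizes differ by at
    most one.  V = N gives the leave-one-out partition.
    """
    _check_v(N, V)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    fold_of = np.empty(N, dtype=int)
    fold_of[perm] = np.arange(N) % V + 1
    return FoldAssignment(fold_of, V, seed)


def stratify_output(y, task: str, n_strata: int = 5) -> np.ndarray:
    """Stratum label per sample.

    Classification strata are the class labels themselves.  Regression
    output is binned into ``n_strata`` quantile groups of consecutive order
    statistics, ties broken by stable sample order; a constant output
    collapses to a single stratum with a warning.
    """
    y = np.asarray(y)
    n = y.size
    if task == CLASSIFICATION:
        return y.astype(object)
    if task != REGRESSION:
        raise ValueError(f"unknown task {task!r}")
    if n_strata < 2:
        raise ValueError("n_strata must be >= 2")
    if n_strata > n:
        raise ValueError(f"n_strata = {n_strata} exceeds N = {n}")
    yf = y.astype(float)
    if np.all(yf == yf[0]):
        warnings.warn("constant output: single stratum", stacklevel=2)
        return np.zeros(n, dtype=object)
    order = np.argsort(yf, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    return (rank * n_strata // n).astype(object)


def make_stratified_folds(
    y, task: str, V: int, seed: int, n_strata: int | None = None
) -> FoldAssignment:
    """V folds each carrying (almost) the same proportion of every stratum.

    Within each stratum the members are shuffled and dealt round-robin; the
    dealing position carries over between strata so total fold sizes stay
    balanced.  Per-(fold, stratum) counts deviate from exact proportionality
    |stratum|/V by strictly less than one.
    """
    y = np.asarray(y)
    n = y.size
    _check_v(n, V)
    if n_strata is None:
        n_strata = min(V, 5)
    strata = stratify_output(y, task, n_strata) if task == REGRESSION else stratify_output(y, task)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    labels = sorted(set(strata), key=str)
    fold_order = rng.permutation(V)  # which fold gets each dealing slot
    pos = 0
    for lab in labels:
        members = np.flatnonzero(strata == lab)
        members = rng.permutation(members)
        for m in members:
            fold_of[m] = fold_order[pos % V] + 1
            pos += 1
    return FoldAssignment(fold_of, V, seed)
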