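"""Dataset container, CSV I/O and synthetic-data generators.

A :class:`Dataset` is the tabular object every protocol consumes: N samples,
P real-valued descriptor columns and one output variable — numeric for
regression, a finite label set for classification.  The generators emulate
the structure of small-molecule QSAR tables: a sparse linear signal with
Gaussian noise (regression), a logistic model with controllable class balance
(classification), and "dirty" descriptor blocks containing known
near-zero-variance and exact linear-combination columns for exercising the
preprocessing filters against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

REGRESSION = "regression"
CLASSIFICATION = "classification"

__all__ = [
    "Dataset", "SyntheticSpec", "GroundTruth",
    "load_dataset", "save_dataset",
    "generate_regression", "generate_classification", "inject_decoys",
]


class DatasetError(ValueError):
    """Raised when a dataset violates its invariants or cannot be loaded."""


@dataclass
class Dataset:
    """N×P descriptor matrix plus one output vector.

    Parameters
    ----------
    X : ndarray of shape (N, P)
        Real-valued descriptors; binary fingerprints are represented as 0/1.
    y : ndarray of shape (N,)
        Float for regression; string labels for classification.
    variable_names : list of str
        Unique column names, length P.
    task : {"regression", "classification"}
    """

    X: np.ndarray
    y: np.ndarray
    variable_names: list[str]
    task: str

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DatasetError("X must be a 2-D matrix")
        n, p = self.X.shape
        if n < 2:
            raise DatasetError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise DatasetError("need at least 1 descriptor column")
        if self.task not in (REGRESSION, CLASSIFICATION):
            raise DatasetError(f"unknown task {self.task!r}")
        if self.task == REGRESSION:
            self.y = np.asarray(self.y, dtype=float)
            if not np.all(np.isfinite(self.y)):
                raise DatasetError("regression output contains non-finite values")
        else:
            self.y = np.asarray(self.y, dtype=object)
        if self.y.shape != (n,):
            raise DatasetError(f"y has shape {self.y.shape}, expected ({n},)")
        if not np.all(np.isfinite(self.X)):
            i, j = np.argwhere(~np.isfinite(self.X))[0]
            raise DatasetError(
                f"missing/non-finite descriptor value at row {i}, "
                f"column {self.variable_names[j]!r}"
            )
        if len(self.variable_names) != p:
            raise DatasetError("variable_names length must equal P")
        if len(set(self.variable_names)) != p:
            raise DatasetError("variable_names must be unique")
        if self.task == CLASSIFICATION and len(set(self.y)) < 2:
            raise DatasetError("classification output needs >= 2 distinct labels")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> list:
        """Sorted label set (classification); canonical lexicographic order."""
        if self.task != CLASSIFICATION:
            raise DatasetError("classes only defined for classification")
        return sorted(set(self.y))

    def subset_rows(self, idx) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset(self.X[idx], self.y[idx], list(self.variable_names), self.task)

    def subset_columns(self, cols) -> "Dataset":
        cols = np.asarray(cols, dtype=int)
        return Dataset(
            self.X[:, cols],
            self.y,
            [self.variable_names[c] for c in cols],
            self.task,
        )

    def to_frame(self, output_column: str = "y") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.variable_names)
        df.insert(0, output_column, self.y)
        return df


def load_dataset(path, output_column: str, task: str) -> Dataset:
    """Read a CSV (header row, '.' decimal) into a :class:`Dataset`.

    The named output column becomes y; every remaining column must be
    numeric and complete.  Row order is preserved.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if output_column not in df.columns:
        raise DatasetError(f"output column {output_column!r} not found in {path}")
    y = df[output_column]
    Xdf = df.drop(columns=[output_column])
    if Xdf.shape[1] < 1:
        raise DatasetError("no descriptor columns in file")
    for col in Xdf.columns:
        na = Xdf[col].isna()
        if na.any():
            row = int(np.argmax(na.to_numpy()))
            raise DatasetError(f"missing value at row {row}, column {col!r}")
        if not pd.api.types.is_numeric_dtype(Xdf[col]):
            raise DatasetError(f"non-numeric descriptor column {col!r}")
    if y.isna().any():
        row = int(np.argmax(y.isna().to_numpy()))
        raise DatasetError(f"missing value at row {row}, column {output_column!r}")
    if task == CLASSIFICATION:
        yv = y.astype(str).to_numpy(dtype=object)
    else:
        yv = y.to_numpy(dtype=float)
    return Dataset(Xdf.to_numpy(dtype=float), yv, list(Xdf.columns), task)


def save_dataset(dataset: Dataset, path, output_column: str = "y") -> None:
    """Write a dataset to CSV losslessly for finite doubles (repr precision)."""
    dataset.to_frame(output_column).to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic dataset with known ground truth.

    ``coefficient_scale`` is the magnitude of each informative coefficient
    (the logistic slope for classification); ``noise_sd`` the Gaussian noise
    standard deviation (regression only); ``intercept`` shifts the logistic
    model to control class balance.  Decoy counts append columns engineered
    to fail the preprocessing filters, with their identities recorded.
    """

    n_samples: int
    n_variables: int
    n_informative: int
    coefficient_scale: float = 1.0
    noise_sd: float = 1.0
    intercept: float = 0.0
    n_nzv_decoys: int = 0
    n_lincomb_decoys: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise DatasetError("n_samples must be >= 2")
        if not (0 <= self.n_informative <= self.n_variables):
            raise DatasetError("need 0 <= n_informative <= n_variables")
        if self.noise_sd < 0:
            raise DatasetError("noise_sd must be >= 0")
        if self.n_nzv_decoys < 0 or self.n_lincomb_decoys < 0:
            raise DatasetError("decoy counts must be >= 0")


@dataclass
class GroundTruth:
    """Bookkeeping for a generated dataset: which columns carry signal,
    which are decoys, and the generating coefficients."""

    informative_idx: list[int]
    beta: np.ndarray
    nzv_idx: list[int] = field(default_factory=list)
    lincomb_idx: list[int] = field(default_factory=list)
    class_counts: dict = field(default_factory=dict)

    @property
    def decoy_idx(self) -> list[int]:
        return list(self.nzv_idx) + list(self.lincomb_idx)


def _base_matrix(spec: SyntheticSpec, rng) -> np.ndarray:
    return rng.standard_normal((spec.n_samples, spec.n_variables))


def _names(p: int) -> list[str]:
    return [f"x{j + 1}" for j in range(p)]


def generate_regression(spec: SyntheticSpec) -> tuple[Dataset, GroundTruth]:
    """y = X·β + ε with exactly ``n_informative`` nonzero coefficients.

    The first ``n_informative`` columns carry coefficient ``coefficient_scale``;
    ε ~ Normal(0, noise_sd²).  Descriptors are iid standard normal, so
    Var(y) = n_informative·coefficient_scale² + noise_sd².  Decoy columns,
    if requested, are appended afterwards with recorded identities.  Same
    seed ⇒ bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    X = _base_matrix(spec, rng)
    beta = np.zeros(spec.n_variables)
    beta[: spec.n_informative] = spec.coefficient_scale
    eps = rng.standard_normal(spec.n_samples) * spec.noise_sd
    y = X @ beta + eps
    ds = Dataset(X, y, _names(spec.n_variables), REGRESSION)
    truth = GroundTruth(list(range(spec.n_informative)), beta)
    return _maybe_decoys(ds, truth, spec)


def generate_classification(
    spec: SyntheticSpec, max_retries: int = 20
) -> tuple[Dataset, GroundTruth]:
    """Two-class labels from a logistic model on the informative columns.

    P(positive | x) = expit(intercept + coefficient_scale · Σ informative x).
    A draw that realises a single class is regenerated with a derived seed up
    to ``max_retries`` times (reported via the retry count implicit in the
    seed path), then raises.  Realised class counts are recorded, and a
    near-degenerate balance (minority < 5%) triggers a warning.
    """
    from scipy.special import expit

    beta = np.zeros(spec.n_variables)
    beta[: spec.n_informative] = spec.coefficient_scale
    for attempt in range(max_retries):
        rng = np.random.default_rng([spec.seed, attempt])
        X = _base_matrix(spec, rng)
        prob = expit(spec.intercept + X @ beta)
        draws = rng.random(spec.n_samples) < prob
        if draws.any() and not draws.all():
            break
    else:
        raise DatasetError(
            f"could not realise two classes in {max_retries} draws; "
            "spec is degenerate (extreme intercept or tiny n_samples)"
        )
    y = np.where(draws, "pos", "neg").astype(object)
    counts = {"pos": int(draws.sum()), "neg": int((~draws).sum())}
    minority = min(counts.values()) / spec.n_samples
    if minority < 0.05:
        warnings.warn(
            f"near-degenerate class balance: minority fraction {minority:.3f}",
            stacklevel=2,
        )
    ds = Dataset(X, y, _names(spec.n_variables), CLASSIFICATION)
    truth = GroundTruth(list(range(spec.n_informative)), beta, class_counts=counts)
    return _maybe_decoys(ds, truth, spec)


def _maybe_decoys(ds, truth, spec):
    if spec.n_nzv_decoys or spec.n_lincomb_decoys:
        ds, nzv_idx, lin_idx = inject_decoys(
            ds, spec.n_nzv_decoys, spec.n_lincomb_decoys, seed=spec.seed + 1
        )
        truth = replace(truth, nzv_idx=nzv_idx, lincomb_idx=lin_idx)
    return ds, truth


def inject_decoys(
    dataset: Dataset, n_nzv: int, n_lincomb: int, seed: int
) -> tuple[Dataset, list[int], list[int]]:
    """Append engineered filter-fodder columns; return their indices.

    Near-zero-variance decoys take two values with a most/second-most common
    frequency ratio above 19 and under 10% distinct values (a constant column
    when N ≤ 20, where two distinct values cannot satisfy both criteria).
    Linear-combination decoys are exact weighted sums of two existing columns.
    """
    if n_lincomb > 0 and dataset.n_variables == 0:
        raise DatasetError("cannot build linear-combination decoys with no columns")
    rng = np.random.default_rng(seed)
    n = dataset.n_samples
    cols, names = [], []
    for i in range(n_nzv):
        a, b = rng.normal(size=2) * 10
        col = np.full(n, a)
        if n > 20:
            # m minority copies with (n-m)/m > 19 and 2/n < 10%
            m = max(1, n // 21)
            pos = rng.choice(n, size=m, replace=False)
            col[pos] = b
        cols.append(col)
        names.append(f"nzv_decoy_{i + 1}")
    for i in range(n_lincomb):
        if dataset.n_variables >= 2:
            c1, c2 = rng.choice(dataset.n_variables, size=2, replace=False)
            w1, w2 = rng.uniform(0.5, 2.0, size=2)
            col = w1 * dataset.X[:, c1] + w2 * dataset.X[:, c2]
        else:
            w1 = rng.uniform(0.5, 2.0)
            col = w1 * dataset.X[:, 0]
        cols.append(col)
        names.append(f"lincomb_decoy_{i + 1}")
    if not cols:
        return dataset, [], []
    X = np.column_stack([dataset.X] + [np.asarray(c) for c in cols])
    ds = Dataset(X, dataset.y, dataset.variable_names + names, dataset.task)
    p0 = dataset.n_variables
    nzv_idx = list(range(p0, p0 + n_nzv))
    lin_idx = list(range(p0 + n_nzv, p0 + n_nzv + n_lincomb))
    return ds, nzv_idx, lin_idx
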