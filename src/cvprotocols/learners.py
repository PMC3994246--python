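"""Model builders with an explicit complexity ordering, and the loss functions.

A grid point (:class:`ParamPoint`) bundles parameter values with an integer
``complexity_rank`` — higher means more complex — so loss ties can always be
broken toward the simpler model.  The ranking follows the usual effective-
degrees-of-freedom direction: more neighbours k, or larger ridge penalty λ,
means a *simpler* model; more PLS components, more selected variables or a
larger SVM cost C means a more complex one.

Ridge regression (closed form), PLS (classical NIPALS) and k-nearest
neighbours are implemented here so the core protocols run self-contained;
ridge-penalised logistic regression and the linear SVM delegate to
scikit-learn behind the same :class:`ModelBuilder` contract.  Every builder
standardises descriptors on the training rows it is given — never on held-out
rows — and all fits are deterministic.

Loss convention: both losses are per-sample means (mean squared residual,
proportion misclassified), so values pool consistently across folds and are
comparable across datasets of different size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import CLASSIFICATION, REGRESSION, Dataset

__all__ = [
    "ParamPoint", "grid_from_values",
    "squared_error_cv_loss", "misclassification_loss", "loss_for_task",
    "RidgeBuilder", "RidgeLogisticBuilder", "PLSBuilder", "KNNBuilder",
    "LinearSVMBuilder", "ridge_lambda_grid", "get_builder", "LEARNERS",
]


# --------------------------------------------------------------------------
# grid points

@dataclass(frozen=True)
class ParamPoint:
    """One candidate parameter setting with its complexity rank."""

    values: tuple[tuple[str, object], ...]
    complexity_rank: int

    @classmethod
    def make(cls, complexity_rank: int, **params) -> "ParamPoint":
        return cls(tuple(sorted(params.items())), complexity_rank)

    def __getitem__(self, key):
        for k, v in self.values:
            if k == key:
                return v
        raise KeyError(key)

    def get(self, key, default=None):
        try:
            return self[key]
        except KeyError:
            return default

    def with_param(self, complexity_rank: int, **extra) -> "ParamPoint":
        merged = dict(self.values)
        merged.update(extra)
        return ParamPoint.make(complexity_rank, **merged)

    @property
    def label(self) -> str:
        return ", ".join(
            f"{k}={v:.6g}" if isinstance(v, float) else f"{k}={v}"
            for k, v in self.values
        )


def grid_from_values(name: str, values, complexity: str = "increasing") -> tuple:
    """Build a 1-D grid of ParamPoints from parameter values in grid order.

    ``complexity="increasing"`` ranks later values as more complex (PLS
    components, variable counts, SVM cost); ``"decreasing"`` ranks them as
    simpler (k in k-NN, ridge λ listed ascending).
    """
    values = list(values)
    k = len(values)
    if complexity == "increasing":
        ranks = range(k)
    elif complexity == "decreasing":
        ranks = range(k - 1, -1, -1)
    else:
        raise ValueError("complexity must be 'increasing' or 'decreasing'")
    return tuple(ParamPoint.make(r, **{name: v}) for r, v in zip(ranks, values))


# --------------------------------------------------------------------------
# losses

def squared_error_cv_loss(y_true, y_pred) -> float:
    """Mean squared residual over the samples."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    return float(np.mean((y_true - y_pred) ** 2))


def misclassification_loss(y_true, y_pred) -> float:
    """Proportion of samples whose predicted label differs from the truth."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    return float(np.mean(y_true != y_pred))


def loss_for_task(task: str):
    return squared_error_cv_loss if task == REGRESSION else misclassification_loss


# --------------------------------------------------------------------------
# standardisation helper (train rows only)

class _Scaler:
    def __init__(self, X: np.ndarray):
        self.mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        self.sd = sd

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mu) / self.sd


def _encode01(y, classes) -> np.ndarray:
    """Two-class labels -> {0, 1} by lexicographic class order."""
    return np.asarray([classes.index(v) for v in y], dtype=float)


# --------------------------------------------------------------------------
# ridge regression (closed form)

class _RidgeModel:
    def __init__(self, scaler, beta, intercept):
        self.scaler, self.beta, self.intercept = scaler, beta, intercept

    def predict(self, X):
        return self.intercept + self.scaler.transform(X) @ self.beta


class RidgeBuilder:
    """Penalised least squares: min ‖y − β₀ − Zβ‖² + λ·N·‖β‖² on
    standardised descriptors Z.  λ = 0 is ordinary least squares; λ → ∞
    shrinks every slope to zero and predicts the training mean."""

    task = REGRESSION
    param_names = ("lambda",)

    def fit(self, train: Dataset, params: ParamPoint):
        lam = float(params["lambda"])
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        scaler = _Scaler(train.X)
        Z = scaler.transform(train.X)
        ybar = float(np.mean(train.y))
        yc = train.y - ybar
        n, p = Z.shape
        A = Z.T @ Z + lam * n * np.eye(p)
        beta = np.linalg.solve(A, Z.T @ yc) if lam > 0 else np.linalg.lstsq(Z, yc, rcond=None)[0]
        return _RidgeModel(scaler, beta, ybar)

    def default_grid(self, dataset: Dataset) -> tuple:
        return ridge_lambda_grid(dataset)


def ridge_lambda_grid(
    dataset: Dataset, n_lambda: int = 100, min_ratio: float = 1e-6
) -> tuple:
    """Log-spaced descending λ grid anchored at a data-derived λ_max.

    λ_max = max_j |⟨z_j, y_c⟩| / N on standardised descriptors — the
    smallest penalty at which a soft-thresholding (lasso-type) fit has
    all-zero slopes, the conventional path anchor.  The grid runs from
    λ_max down to λ_max·min_ratio in ``n_lambda`` log-uniform steps and is
    computed once from the dataset it is given; complexity increases as λ
    decreases.
    """
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    scaler = _Scaler(dataset.X)
    Z = scaler.transform(dataset.X)
    n = dataset.n_samples
    if dataset.task == REGRESSION:
        yc = np.asarray(dataset.y, dtype=float) - np.mean(dataset.y)
    else:
        y01 = _encode01(dataset.y, dataset.classes[:2]) if len(dataset.classes) == 2 \
            else np.asarray([dataset.classes.index(v) for v in dataset.y], dtype=float)
        yc = y01 - y01.mean()
    lam_max = float(np.max(np.abs(Z.T @ yc)) / n)
    if lam_max <= 0:
        lam_max = 1.0
    lams = np.geomspace(lam_max, lam_max * min_ratio, n_lambda)
    return grid_from_values("lambda", [float(v) for v in lams], complexity="increasing")


# --------------------------------------------------------------------------
# ridge-penalised logistic regression (scikit-learn behind the contract)

class _SklearnModel:
    def __init__(self, scaler, est):
        self.scaler, self.est = scaler, est

    def predict(self, X):
        return np.asarray(self.est.predict(self.scaler.transform(X)), dtype=object)


class RidgeLogisticBuilder:
    """L2-penalised logistic regression; λ maps to scikit-learn's C as
    C = 1/(λ·N), matching the ridge penalty scaling ‖·‖²·λ·N."""

    task = CLASSIFICATION
    param_names = ("lambda",)

    def fit(self, train: Dataset, params: ParamPoint):
        from sklearn.linear_model import LogisticRegression

        lam = float(params["lambda"])
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        scaler = _Scaler(train.X)
        Z = scaler.transform(train.X)
        C = 1e12 if lam == 0 else 1.0 / (lam * train.n_samples)
        est = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-10)
        est.fit(Z, np.asarray(train.y, dtype=str))
        return _SklearnModel(scaler, est)

    def default_grid(self, dataset: Dataset) -> tuple:
        return ridge_lambda_grid(dataset)


# --------------------------------------------------------------------------
# partial least squares (NIPALS, univariate response)

class _PLSModel:
    def __init__(self, scaler, beta, intercept):
        self.scaler, self.beta, self.intercept = scaler, beta, intercept

    def predict(self, X):
        return self.intercept + self.scaler.transform(X) @ self.beta


class PLSBuilder:
    """Partial least squares regression via the classical iterative
    (NIPALS) algorithm: components are built one at a time as linear
    combinations of the descriptors maximising covariance with the output,
    the descriptor matrix is deflated, and the scores are mutually
    orthogonal.  Each added component increases model complexity; with
    n_components = rank(X) the fit coincides with least squares."""

    task = REGRESSION
    param_names = ("n_components",)

    def fit(self, train: Dataset, params: ParamPoint):
        a = int(params["n_components"])
        n, p = train.X.shape
        if not (1 <= a <= min(n - 1, p)):
            raise ValueError(
                f"n_components = {a} out of range [1, {min(n - 1, p)}]"
            )
        scaler = _Scaler(train.X)
        E = scaler.transform(train.X)
        ybar = float(np.mean(train.y))
        f = np.asarray(train.y, dtype=float) - ybar
        W = np.zeros((p, a))
        P = np.zeros((p, a))
        q = np.zeros(a)
        for c in range(a):
            w = E.T @ f
            nw = np.linalg.norm(w)
            if nw < 1e-12:  # response fully deflated
                W, P, q = W[:, :c], P[:, :c], q[:c]
                break
            w /= nw
            t = E @ w
            tt = float(t @ t)
            pvec = E.T @ t / tt
            qc = float(t @ f) / tt
            E = E - np.outer(t, pvec)
            f = f - qc * t
            W[:, c], P[:, c], q[c] = w, pvec, qc
        if W.shape[1] == 0:
            beta = np.zeros(p)
        else:
            beta = W @ np.linalg.solve(P.T @ W, q)
        return _PLSModel(scaler, beta, ybar)

    def default_grid(self, dataset: Dataset, max_components: int = 60) -> tuple:
        top = min(max_components, dataset.n_samples - 1, dataset.n_variables)
        return grid_from_values("n_components", range(1, top + 1), "increasing")


# --------------------------------------------------------------------------
# k-nearest neighbours

class _KNNModel:
    def __init__(self, X, y, k, task, scaler):
        self.X, self.y, self.k, self.task, self.scaler = X, y, k, task, scaler

    def predict(self, X):
        Q = self.scaler.transform(X)
        out = []
        for row in Q:
            d = np.sqrt(((self.X - row) ** 2).sum(axis=1))
            nn = np.argsort(d, kind="stable")[: self.k]  # distance ties -> lower index
            yv = self.y[nn]
            if self.task == REGRESSION:
                out.append(float(np.mean(yv.astype(float))))
            else:
                labs, counts = np.unique(yv.astype(str), return_counts=True)
                out.append(sorted(labs[counts == counts.max()])[0])  # tie -> smallest label
        dtype = float if self.task == REGRESSION else object
        return np.asarray(out, dtype=dtype)


class KNNBuilder:
    """k-nearest-neighbour prediction: the mean (regression) or majority
    label (classification, ties to the lexicographically smallest) of the k
    closest training rows in standardised Euclidean distance.  Larger k is
    the simpler model (effective degrees of freedom ≈ N/k)."""

    param_names = ("k",)

    def __init__(self, task: str = REGRESSION):
        self.task = task

    def fit(self, train: Dataset, params: ParamPoint):
        k = int(params["k"])
        if not (1 <= k <= train.n_samples):
            raise ValueError(f"k = {k} out of range [1, {train.n_samples}]")
        scaler = _Scaler(train.X)
        return _KNNModel(scaler.transform(train.X), train.y, k, self.task, scaler)

    def default_grid(self, dataset: Dataset) -> tuple:
        ks = [k for k in (1, 3, 5, 7, 9) if k <= dataset.n_samples]
        return grid_from_values("k", ks, complexity="decreasing")


# --------------------------------------------------------------------------
# linear SVM (scikit-learn behind the contract)

class LinearSVMBuilder:
    """Linear support vector classifier; the cost C is the only tuning
    parameter and larger C (less regularisation) is the more complex model.
    The grid the protocols typically scan is {0.5, 1, 2, 4, 8, 16}."""

    task = CLASSIFICATION
    param_names = ("cost",)
    DEFAULT_COSTS = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)

    def fit(self, train: Dataset, params: ParamPoint):
        from sklearn.svm import SVC

        C = float(params["cost"])
        if C <= 0:
            raise ValueError("cost must be > 0")
        scaler = _Scaler(train.X)
        est = SVC(kernel="linear", C=C)
        est.fit(scaler.transform(train.X), np.asarray(train.y, dtype=str))
        return _SklearnModel(scaler, est)

    def default_grid(self, dataset: Dataset) -> tuple:
        return grid_from_values("cost", self.DEFAULT_COSTS, complexity="increasing")


# --------------------------------------------------------------------------
# registry

LEARNERS = {
    "ridge": RidgeBuilder,
    "ridge_logistic": RidgeLogisticBuilder,
    "pls": PLSBuilder,
    "knn": KNNBuilder,
    "linear_svm": LinearSVMBuilder,
}


def get_builder(name: str, task: str | None = None):
    """Instantiate a registered model builder by name."""
    try:
        cls = LEARNERS[name]
    except KeyError:
        raise KeyError(f"unknown learner {name!r}; choose from {sorted(LEARNERS)}")
    if cls is KNNBuilder:
        return cls(task or REGRESSION)
    return cls()
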