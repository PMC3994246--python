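"""Independent literal-transcription oracles for the four CV procedures.

Each oracle re-derives the result with plain nested loops and its own
learner/selector code (a from-scratch k-nearest-neighbour predictor and a
definitional Pearson ranking), sharing only the fold-partition and seed-
derivation primitives with the package so that both sides see the same
pseudo-random splits.  The pooling, averaging, argmin and tie-break logic —
the substance of the algorithms — is written here from scratch.
"""

import numpy as np
from scipy import stats

from cvprotocols._seeds import derive_seed
from cvprotocols.partitioning import make_folds, make_stratified_folds


def knn_predict(Xtr, ytr, Xte, k):
    """Mean of the k nearest training rows in standardised Euclidean
    distance; stable argsort so distance ties go to the lower row index."""
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z, Q = (Xtr - mu) / sd, (Xte - mu) / sd
    out = np.empty(len(Q))
    for i, row in enumerate(Q):
        d = np.sqrt(((Z - row) ** 2).sum(axis=1))
        nn = np.argsort(d, kind="stable")[:k]
        out[i] = ytr[nn].mean()
    return out


def mse(y, yhat):
    return float(np.mean((np.asarray(y, float) - np.asarray(yhat, float)) ** 2))


def argmin_simplest(losses, complexity_ranks):
    """Index of the minimal loss; exact ties to the lowest complexity rank."""
    best = min(losses)
    tied = [i for i, v in enumerate(losses) if v == best]
    return min(tied, key=lambda i: complexity_ranks[i])


def pearson_rank(X, y, p):
    """Definitional |r| ranking: scipy pearsonr per column, ties by index."""
    scores = []
    for j in range(X.shape[1]):
        if np.std(X[:, j]) == 0:
            scores.append(0.0)
        else:
            scores.append(abs(stats.pearsonr(X[:, j], y)[0]))
    order = sorted(range(X.shape[1]), key=lambda j: (-scores[j], j))
    return order[:p]


def single_cv_knn(X, y, ks, V, seed):
    """One V-fold CV pass over a k-NN grid: pooled per-sample mean loss."""
    N = len(y)
    folds = make_folds(N, V, seed)
    preds = np.zeros((len(ks), N))
    for f, tr, te in folds.iter_folds():
        for i, k in enumerate(ks):
            preds[i, te] = knn_predict(X[tr], y[tr], X[te], k)
    return [mse(y, preds[i]) for i in range(len(ks))]


def repeated_grid_search_knn(X, y, ks, V, Nexp, base_seed):
    """Repeated grid-search CV: loss table, means and the chosen k.

    k-NN complexity decreases with k, so ties go to the largest k.
    """
    ranks = [-k for k in ks]  # larger k = simpler = lower rank
    table = np.array([
        single_cv_knn(X, y, ks, V, derive_seed(base_seed, "repeat", r))
        for r in range(Nexp)
    ])
    means = table.mean(axis=0)
    idx = argmin_simplest(list(means), ranks)
    return table, means, ks[idx]


def single_nested_cv_knn(X, y, ks, V1, Nexp1, V2, seed, n_strata=None):
    """One stratified nested CV error for the k-NN selection protocol."""
    N = len(y)
    folds = make_stratified_folds(y, "regression", V2, seed, n_strata=n_strata)
    preds = np.zeros(N)
    for f, tr, te in folds.iter_folds():
        _, _, k_best = repeated_grid_search_knn(
            X[tr], y[tr], ks, V1, Nexp1, derive_seed(seed, "inner", f)
        )
        preds[te] = knn_predict(X[tr], y[tr], X[te], k_best)
    return mse(y, preds)


def grid_search_with_selection_knn(X, y, n_values, ks, V, Nexp, base_seed):
    """Variable selection + tuning on the 2-D (n, k) grid, selector on L only.

    Returns the Nexp × (n, k) loss table (dict keyed by pair) and the chosen
    pair, ties broken by (fewer variables, then larger k).
    """
    N = len(y)
    pairs = [(n, k) for n in sorted(n_values) for k in ks]
    table = np.zeros((Nexp, len(pairs)))
    for r in range(Nexp):
        seed = derive_seed(base_seed, "repeat", r)
        folds = make_folds(N, V, seed)
        preds = np.zeros((len(pairs), N))
        for f, tr, te in folds.iter_folds():
            for i, (n, k) in enumerate(pairs):
                cols = pearson_rank(X[tr], y[tr], n)
                preds[i, te] = knn_predict(X[np.ix_(tr, cols)], y[tr],
                                           X[np.ix_(te, cols)], k)
        table[r] = [mse(y, preds[i]) for i in range(len(pairs))]
    means = table.mean(axis=0)
    ranks = [(n, -k) for n, k in pairs]  # lexicographic: fewer vars, larger k
    idx = argmin_simplest(list(means), ranks)
    return table, means, pairs[idx]


def double_cv_knn(X, y, n_values, ks, V1, V2, base_seed):
    """Stone's double CV transcribed step by step for the k-NN grid."""
    N = len(y)
    kranks = [-k for k in ks]
    outer = make_folds(N, V1, derive_seed(base_seed, "dcv", 0))
    preds = {n: np.zeros(N) for n in n_values}
    for f, tr, te in outer.iter_folds():
        for pi, n in enumerate(sorted(n_values)):
            cols = pearson_rank(X[tr], y[tr], n)
            Xp, yp = X[np.ix_(tr, cols)], y[tr]
            inner = make_folds(len(yp), V2, derive_seed(base_seed, "dcv", 1, f, pi))
            ipred = np.zeros((len(ks), len(yp)))
            for g, itr, ite in inner.iter_folds():
                for i, k in enumerate(ks):
                    ipred[i, ite] = knn_predict(Xp[itr], yp[itr], Xp[ite], k)
            ilosses = [mse(yp, ipred[i]) for i in range(len(ks))]
            k_best = ks[argmin_simplest(ilosses, kranks)]
            preds[n][te] = knn_predict(Xp, yp, X[np.ix_(te, cols)], k_best)
    step1 = {n: mse(y, preds[n]) for n in n_values}
    best = min(step1.values())
    p_chosen = min(n for n, v in step1.items() if v == best)

    cols = pearson_rank(X, y, p_chosen)
    Xp = X[:, cols]
    folds2 = make_folds(N, V1, derive_seed(base_seed, "dcv", 2))
    fpred = np.zeros((len(ks), N))
    for f, tr, te in folds2.iter_folds():
        for i, k in enumerate(ks):
            fpred[i, te] = knn_predict(Xp[tr], y[tr], Xp[te], k)
    step2 = [mse(y, fpred[i]) for i in range(len(ks))]
    k_chosen = ks[argmin_simplest(step2, kranks)]
    return p_chosen, k_chosen, step1, step2
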