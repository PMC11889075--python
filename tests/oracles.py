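"""Independent brute-force oracles used only by the tests.

These deliberately re-derive the estimator definitions with plain Python
loops and textbook formulas, separate from the library's vectorized
implementations, so agreement is a genuine cross-check.
"""

from itertools import combinations

import numpy as np


def brute_nn_pairs(scores, T):
    """Exhaustive nearest-opposite-neighbour search with the lowest-index
    tie rule, by direct scan."""
    scores = [float(s) for s in scores]
    T = [int(t) for t in T]
    n = len(T)
    pairs = []
    for i in range(n):
        best, best_d = None, None
        for j in range(n):
            if T[j] == T[i]:
                continue
            d = abs(scores[i] - scores[j])
            if best is None or d < best_d or (d == best_d and j < best):
                best, best_d = j, d
        if best is None:
            raise ValueError("no opposite-group unit")
        pairs.append(best)
    return pairs


def brute_matched_ate(scores, T, Y, X=None):
    """Matching ATE by exhaustive neighbour scan; optional regression
    bias correction re-implemented from the definition (within-group OLS
    of Y on [1, X], adjustment mu(X_i) − mu(X_j), applied only when a
    group has strictly more units than regression parameters)."""
    pairs = brute_nn_pairs(scores, T)
    T = np.asarray(T, dtype=int)
    Y = np.asarray(Y, dtype=float)
    mu = {0: None, 1: None}
    if X is not None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(T):
            X = X.T
        A = np.column_stack([np.ones(len(T)), X])
        for g in (0, 1):
            rows = T == g
            if rows.sum() > A.shape[1]:
                coef, *_ = np.linalg.lstsq(A[rows], Y[rows], rcond=None)
                mu[g] = A @ coef
    diffs = []
    for i, j in enumerate(pairs):
        if T[i] == 1:
            imput = Y[j] + (mu[0][i] - mu[0][j] if mu[0] is not None else 0.0)
            diffs.append(Y[i] - imput)
        else:
            imput = Y[j] + (mu[1][i] - mu[1][j] if mu[1] is not None else 0.0)
            diffs.append(imput - Y[i])
    return float(np.mean(diffs))


def exact_permutation_pvalue(ate_fn, T, observed):
    """Exact two-sided permutation p-value by full enumeration of all
    treatment assignments with the observed treated count.

    ``ate_fn(T_perm)`` must return the estimator value for a candidate
    assignment.  Returns the unsmoothed exhaustive fraction.
    """
    T = np.asarray(T, dtype=int)
    n, k = len(T), int(T.sum())
    hits = total = 0
    for pos in combinations(range(n), k):
        Tp = np.zeros(n)
        Tp[list(pos)] = 1.0
        total += 1
        if abs(ate_fn(Tp)) >= abs(observed) - 1e-12:
            hits += 1
    return hits / total


def logistic_loglik(X, T, beta):
    """Bernoulli log-likelihood of a logistic model with intercept."""
    A = np.column_stack([np.ones(len(T)), np.atleast_2d(X).reshape(len(T), -1)])
    eta = A @ np.asarray(beta, dtype=float)
    return float(np.sum(T * eta - np.log1p(np.exp(eta))))
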