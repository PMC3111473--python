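"""Independent brute-force reference implementations used only by the tests.

Each oracle is written as a direct, loop-based transcription of the defining
formula, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def scalar_loo_D(values: np.ndarray, is_case: np.ndarray, i: int) -> float:
    """Leave-one-out standardized-mean distance score for sample i, loop by loop."""
    n, s = values.shape
    ds = []
    for j in range(s):
        y = values[i, j]
        if np.isnan(y):
            continue
        case_pool = [
            values[k, j]
            for k in range(n)
            if is_case[k] and k != i and not np.isnan(values[k, j])
        ]
        ctrl_pool = [
            values[k, j]
            for k in range(n)
            if not is_case[k] and k != i and not np.isnan(values[k, j])
        ]
        if not case_pool or not ctrl_pool:
            continue
        g = sum(case_pool) / len(case_pool)
        f = sum(ctrl_pool) / len(ctrl_pool)
        ds.append(abs(y - f) - abs(y - g))
    arr = np.array(ds)
    mean = arr.mean()
    sd = arr.std(ddof=1)
    if sd < 1e-12:
        return 0.0 if abs(mean) < 1e-12 else float(np.sign(mean) * 1e6)
    return float(mean / (sd / np.sqrt(len(arr))))


def midrank_rank_sum(D: np.ndarray, is_case: np.ndarray) -> float:
    """Rank-sum of the cases with midranks, from the counting definition:
    rank(x) = #{y < x} + (#{y == x} + 1) / 2 over all samples including x."""
    W = 0.0
    for i in range(len(D)):
        if not is_case[i]:
            continue
        less = sum(1 for v in D if v < D[i])
        equal = sum(1 for v in D if v == D[i])
        W += less + (equal + 1) / 2.0
    return W


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg q-values straight from the step-up definition."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = np.inf
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = m * p[idx] / rank_from_top
        running_min = min(running_min, val)
        q[idx] = min(running_min, 1.0)
    return q


def irls_logistic(D: np.ndarray, y: np.ndarray, tol: float = 1e-12, max_iter: int = 200):
    """Two-parameter logistic fit by iteratively reweighted least squares.

    Returns (intercept, slope, slope standard error).
    """
    X = np.column_stack([np.ones_like(D), D])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtWX = X.T @ (X * w[:, None])
        grad = X.T @ (y - mu)
        step = np.linalg.solve(XtWX, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta[0], beta[1], np.sqrt(cov[1, 1])


def pairwise_relative_distance(values: np.ndarray, is_case: np.ndarray, metric: str):
    """Per-sample mean distance to other controls minus to other cases, by loops."""
    n, s = values.shape

    def dist(a, b):
        diffs = [abs(x - y) for x, y in zip(a, b) if not (np.isnan(x) or np.isnan(y))]
        if metric == "manhattan":
            return sum(diffs) / len(diffs)
        if metric == "euclidean":
            return (sum(d * d for d in diffs) / len(diffs)) ** 0.5
        raise ValueError(metric)

    out = np.empty(n)
    for i in range(n):
        to_case = [dist(values[i], values[k]) for k in range(n) if is_case[k] and k != i]
        to_ctrl = [dist(values[i], values[k]) for k in range(n) if not is_case[k] and k != i]
        out[i] = np.mean(to_ctrl) - np.mean(to_case)
    return out
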