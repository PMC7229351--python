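"""Independent reference implementations used as test oracles.

These deliberately avoid the package's algorithms: textbook formulas,
exhaustive enumeration and normal-equations algebra, kept simple and slow.
"""

from __future__ import annotations

import numpy as np


def pearson_r_textbook(x, y) -> float:
    """Covariance over product of standard deviations, written out."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((x - mx) * (y - my)) / n
    sx = (sum((x - mx) ** 2) / n) ** 0.5
    sy = (sum((y - my) ** 2) / n) ** 0.5
    return cov / (sx * sy)


def latency_enumeration(layers) -> np.ndarray:
    """Fastest arrival layer over all time-respecting paths, by recursive
    enumeration (strictly increasing layers, one edge per layer, waiting
    free).  Branches that cannot improve the best-known arrival at a node
    are pruned, which is sound because an earlier arrival permits every
    continuation a later one does."""
    layers = np.asarray(layers).astype(bool)
    T, N, _ = layers.shape
    D = np.full((N, N), np.inf)
    np.fill_diagonal(D, 0.0)
    for src in range(N):
        best = D[src]

        def rec(node, last_layer):
            for t in range(last_layer + 1, T + 1):
                for nb in np.flatnonzero(layers[t - 1][node]):
                    if t < best[nb]:
                        best[nb] = t
                        rec(nb, t)

        rec(src, 0)
    return D


def tcc_direct(layers) -> np.ndarray:
    """Nodal temporal correlation by direct per-step loops."""
    layers = np.asarray(layers).astype(int)
    T, N, _ = layers.shape
    C = np.zeros(N)
    for i in range(N):
        total = 0.0
        for t in range(T - 1):
            overlap = sum(layers[t, i, j] * layers[t + 1, i, j] for j in range(N))
            deg_a = layers[t, i].sum()
            deg_b = layers[t + 1, i].sum()
            if deg_a > 0 and deg_b > 0:
                total += overlap / np.sqrt(deg_a * deg_b)
        C[i] = total / (T - 1)
    return C


def temporal_variability_direct(layers) -> np.ndarray:
    """Nodal temporal variability by explicit pairwise profile correlation."""
    layers = np.asarray(layers, float)
    T, N, _ = layers.shape
    V = np.zeros(N)
    for k in range(N):
        profiles = [np.delete(layers[t, k], k) for t in range(T)]
        acc = 0.0
        npairs = 0
        for t in range(T):
            for u in range(t + 1, T):
                acc += pearson_r_textbook(profiles[t], profiles[u])
                npairs += 1
        V[k] = 1.0 - acc / npairs
    return V


def top_k_edges(weights, k) -> set:
    """Top-k undirected edges by weight, ties broken by ascending (i, j)."""
    N = weights.shape[0]
    edges = [
        (weights[i, j], i, j) for i in range(N) for j in range(i + 1, N)
    ]
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    return {(i, j) for _, i, j in edges[:k]}


def ancova_f_normal_equations(y, X_full, group_idx):
    """Extra-sum-of-squares F for one column, via explicit normal equations."""
    y = np.asarray(y, float)
    X = np.asarray(X_full, float)
    n, p = X.shape
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    rss_full = float(((y - X @ beta) ** 2).sum())
    Xr = np.delete(X, group_idx, axis=1)
    br = np.linalg.solve(Xr.T @ Xr, Xr.T @ y)
    rss_red = float(((y - Xr @ br) ** 2).sum())
    df2 = n - p
    F = (rss_red - rss_full) / (rss_full / df2)
    return F, df2, float(beta[group_idx])


def bh_stepup(p) -> np.ndarray:
    """Benjamini-Hochberg step-up, written from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def average_ranks(x) -> np.ndarray:
    """Average ranks (1-based) with ties sharing the mean rank."""
    x = np.asarray(x, float)
    n = len(x)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[order[j + 1]] == x[order[i]]:
            j += 1
        mean_rank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def partial_spearman_steps(x, y, Z=None):
    """Rank everything, residualize on [1, rank(Z)] via pseudo-inverse,
    correlate the residuals."""
    xr = average_ranks(x)
    yr = average_ranks(y)
    n = len(xr)
    if Z is None:
        design = np.ones((n, 1))
    else:
        Zr = np.column_stack([average_ranks(c) for c in np.asarray(Z, float).T])
        design = np.column_stack([np.ones(n), Zr])
    H = design @ np.linalg.pinv(design)
    rx = xr - H @ xr
    ry = yr - H @ yr
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
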