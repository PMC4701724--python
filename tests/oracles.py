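"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid scipy/sklearn correlation and decomposition
routines: ranks are computed by sorting, tau by enumerating all pairs, and
the PCA oracle by eigendecomposition of the explicitly formed correlation
matrix.
"""

from __future__ import annotations

import math

import numpy as np


def average_ranks(x) -> list[float]:
    """Ranks 1..n with ties sharing the mean of their positions."""
    x = list(x)
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        mean_rank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def pearson_bruteforce(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman_bruteforce(x, y) -> float:
    """Pearson correlation of average ranks."""
    return pearson_bruteforce(average_ranks(x), average_ranks(y))


def kendall_taub_bruteforce(x, y) -> float:
    """Tau-b by enumerating every pair of index pairs."""
    n = len(x)
    concordant = discordant = 0
    ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[j] - x[i]
            dy = y[j] - y[i]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (concordant - discordant) / denom


def pca_bruteforce(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(eigenvalues desc, loading columns) of the correlation matrix of X,
    formed explicitly and decomposed with a symmetric eigensolver."""
    X = np.asarray(X, dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = Z.T @ Z / (len(X) - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]
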