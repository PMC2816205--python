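"""Independent brute-force reference implementations.

Everything here is written with plain Python loops and elementary formulas,
deliberately sharing no code path with the package: distances are summed
term by term, neighbor sets come from full sorts, predictions from explicit
averaging, and regression from the normal equations.  These serve as oracles
for the vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def euclidean(u, v) -> float:
    total = 0.0
    for a, b in zip(u, v):
        total += (a - b) ** 2
    return math.sqrt(total)


def combined_distances(profiles: np.ndarray) -> np.ndarray:
    """Gene x gene distances via per-element loops over concatenated profiles."""
    n = profiles.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = euclidean(profiles[i], profiles[j])
            out[i, j] = out[j, i] = d
    return out


def _ranked(dm, i, allowed):
    """Indices in `allowed` sorted by (distance to i, index)."""
    return [j for _, j in sorted((dm[i][j], j) for j in allowed)]


def knn(dm, i, k, forbidden=()):
    allowed = [j for j in range(len(dm)) if j != i and j not in set(forbidden) - {i}]
    return _ranked(dm, i, allowed)[:k]


def top_lists(dm, K):
    """Top-K lists over all genes (self excluded), full-sort based."""
    n = len(dm)
    return [
        _ranked(dm, i, [j for j in range(n) if j != i])[:K]
        for i in range(n)
    ]


def mutual_knn(dm, i, K, fallback, forbidden=()):
    tops = top_lists(dm, K)
    banned = set(forbidden) - {i}
    mutual = {j for j in tops[i] if j not in banned and i in tops[j]}
    floor = set(knn(dm, i, fallback, forbidden))
    return mutual | floor


def dense_subnet(dm, i, K, m, forbidden=()):
    candidates = knn(dm, i, K, forbidden)
    tops = top_lists(dm, K)
    cand = set(candidates)
    degree = {}
    for a in candidates:
        deg = 0
        for b in candidates:
            if b != a and (b in tops[a] or a in tops[b]):
                deg += 1
        degree[a] = deg
    ranked = sorted(candidates, key=lambda j: (-degree[j], dm[i][j], j))
    return ranked[:m]


def average_profiles(values: np.ndarray, members) -> np.ndarray:
    """Element-wise mean of selected rows, accumulated with Python floats."""
    members = list(members)
    out = []
    for t in range(values.shape[1]):
        s = 0.0
        for j in members:
            s += float(values[j, t])
        out.append(s / len(members))
    return np.array(out)


def normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients via (X'X)^-1 X'y — a different route than lstsq/QR."""
    XtX = X.T @ X
    Xty = X.T @ y
    return np.linalg.solve(XtX, Xty)


def spearman(x, y) -> float:
    """Textbook Spearman: Pearson of midranks, computed from first principles."""
    return pearson(_midranks(x), _midranks(y))


def _midranks(v):
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
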