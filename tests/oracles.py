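"""Independent brute-force oracles used to validate the fast implementations.

Each oracle recomputes a quantity from first principles (normal equations,
full hypergeometric enumeration, naive agglomeration) and must never call
the code path it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def ols_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int]:
    """Slope/se/p of y ~ 1 + x via explicit normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    XtX = X.T @ X
    coef = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ coef
    df = n - 2
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(XtX)
    beta = float(coef[1])
    se = float(np.sqrt(cov[1, 1]))
    t = beta / se if se > 0 else np.inf
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta, se, p, df


def fisher_oracle(a: int, b: int, c: int, d: int, slack: float = 1e-12) -> float:
    """Two-sided Fisher p by full enumeration of tables with fixed margins.

    Sums hypergeometric probabilities of every table whose probability is
    <= that of the observed table (within a small numeric slack).
    """
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    probs = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    return float(probs[probs <= p_obs * (1.0 + slack)].sum())


def average_linkage_oracle(D: np.ndarray, K: int) -> list[frozenset]:
    """Naive agglomerative average-linkage clustering.

    Starts from singletons and repeatedly merges the pair of clusters with
    the smallest mean pairwise distance, recomputed from scratch each step.
    Returns the partition with K clusters as a set of frozensets of row
    indices.  Assumes no exact ties among candidate merge distances.
    """
    clusters: list[set[int]] = [{i} for i in range(D.shape[0])]
    while len(clusters) > K:
        best = None
        best_d = np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([D[p, q] for p in clusters[i] for q in clusters[j]])
                if d < best_d:
                    best_d = d
                    best = (i, j)
        i, j = best
        clusters[i] |= clusters[j]
        del clusters[j]
    return sorted((frozenset(c) for c in clusters), key=min)


def within_dispersion_oracle(X: np.ndarray, labels: np.ndarray) -> float:
    """Gap-statistic W_k from its pairwise definition:
    sum over clusters of (sum of all pairwise squared Euclidean distances)
    / (2 * cluster size)."""
    total = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        m = len(pts)
        pair_sum = 0.0
        for i in range(m):
            for j in range(m):
                pair_sum += float(((pts[i] - pts[j]) ** 2).sum())
        total += pair_sum / (2 * m)
    return total


def partition_pairs(labels_or_sets) -> set[frozenset]:
    """Co-membership pair set of a partition, for label-free comparison."""
    if isinstance(labels_or_sets, dict):
        groups: dict[object, list] = {}
        for item, lab in labels_or_sets.items():
            groups.setdefault(lab, []).append(item)
        sets = groups.values()
    elif hasattr(labels_or_sets, "dtype") or (
        labels_or_sets and not isinstance(next(iter(labels_or_sets)), frozenset)
    ):
        arr = np.asarray(labels_or_sets)
        sets = [np.flatnonzero(arr == lab).tolist() for lab in np.unique(arr)]
    else:
        sets = labels_or_sets
    pairs = set()
    for s in sets:
        s = sorted(s)
        for i in range(len(s)):
            for j in range(i + 1, len(s)):
                pairs.add(frozenset((s[i], s[j])))
    return pairs
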