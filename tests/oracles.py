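"""Independent brute-force reference implementations used by the tests.

Every function here is O(n^2) and dead simple on purpose: they are the
oracles against which the KD-tree-based production code is checked, and must
not share code with it.
"""

import numpy as np


def mean_knn_distance_brute(points: np.ndarray, k: int) -> np.ndarray:
    n = len(points)
    out = np.empty(n)
    for i in range(n):
        d = np.sqrt(((points - points[i]) ** 2).sum(axis=1))
        d = np.delete(d, i)
        out[i] = np.sort(d)[:k].mean()
    return out


def statistical_filter_brute(points: np.ndarray, k: int, m: float):
    """Returns (kept indices, removed indices) per the sigma-band rule."""
    md = mean_knn_distance_brute(points, k)
    mu, sigma = md.mean(), md.std()
    if sigma == 0.0:
        removed = np.empty(0, dtype=int)
    else:
        removed = np.flatnonzero((md < mu - m * sigma) | (md > mu + m * sigma))
    kept = np.setdiff1d(np.arange(len(points)), removed)
    return kept, removed


def clusters_brute(points: np.ndarray, tol: float, min_size: int, max_size=None):
    """Union-find over the thresholded distance matrix; same output contract
    as euclidean_cluster (sorted index arrays, size-descending order)."""
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        d = np.sqrt(((points - points[i]) ** 2).sum(axis=1))
        for j in np.flatnonzero(d <= tol):
            ra, rb = find(i), find(int(j))
            if ra != rb:
                parent[ra] = rb
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for idx in groups.values():
        if len(idx) < min_size:
            continue
        if max_size is not None and len(idx) > max_size:
            continue
        out.append(np.sort(np.array(idx)))
    out.sort(key=lambda c: (-len(c), int(c[0])))
    return out


def knn_brute(points: np.ndarray, i: int, k: int) -> np.ndarray:
    """k nearest to point i, self excluded, ties to the lower index."""
    d2 = ((points - points[i]) ** 2).sum(axis=1)
    idx = np.array([j for j in range(len(points)) if j != i])
    order = sorted(idx, key=lambda j: (d2[j], j))
    return np.array(order[:k])


def feature_points_brute(points: np.ndarray, s: np.ndarray, defined: np.ndarray, k: int):
    """Indices whose S strictly exceeds the neighbour max (NaN-aware scan)."""
    out = []
    for i in range(len(points)):
        if not defined[i]:
            continue
        nbr = knn_brute(points, i, k)
        vals = [s[j] for j in nbr if defined[j]]
        if not vals or s[i] > max(vals):
            out.append(i)
    return np.array(out, dtype=int)
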