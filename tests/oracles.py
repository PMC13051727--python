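"""Independent brute-force oracles used to validate the pipeline.

Each function here recomputes a quantity by enumeration or naive
definition-chasing, deliberately sharing no code path with the package.
"""

from itertools import permutations, product

import numpy as np


def ks_d_ecdf_sweep(x, y):
    """Two-sample K-S D by sweeping every observed value through both ECDFs."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.sum(x <= t) / x.size
        fy = np.sum(y <= t) / y.size
        best = max(best, abs(fx - fy))
    return best


def complete_linkage_heights(X):
    """O(n^3) naive complete-linkage agglomeration; returns merge heights."""
    X = np.asarray(X, dtype=float)
    clusters = [[i] for i in range(X.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(
                    np.linalg.norm(X[i] - X[j])
                    for i in clusters[a]
                    for j in clusters[b]
                )
                if d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights)


def kmeans_wcss_exhaustive(X, k):
    """Minimum WCSS over every assignment of n points to k labels."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    best = np.inf
    for labels in product(range(k), repeat=n):
        labels = np.asarray(labels)
        if len(set(labels.tolist())) < k:
            continue  # k-means keeps every cluster non-empty
        wcss = 0.0
        for c in range(k):
            pts = X[labels == c]
            wcss += np.sum((pts - pts.mean(axis=0)) ** 2)
        best = min(best, wcss)
    return best


def assignment_cost_brute_force(dist):
    """Minimum total cost over all injective row->column assignments."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] > dist.shape[1]:
        dist = dist.T
    n_rows, n_cols = dist.shape
    best = np.inf
    for perm in permutations(range(n_cols), n_rows):
        cost = sum(dist[i, j] for i, j in enumerate(perm))
        best = min(best, cost)
    return best


def rasterized_disk_area(radius):
    """Pixel count of the lattice disk x^2 + y^2 <= r^2."""
    count = 0
    for yy in range(-radius, radius + 1):
        for xx in range(-radius, radius + 1):
            if yy * yy + xx * xx <= radius * radius:
                count += 1
    return count
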