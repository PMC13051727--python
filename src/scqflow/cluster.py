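"""Subpopulation discovery on normalized expression.

Two complementary views of structure in the (cells x genes) expression
matrix:

* **hierarchical clustergrams** — agglomerative complete-linkage trees on
  Euclidean distances, used to order rows/columns of heatmaps;
* **k-means partitions** — hard assignments minimizing the within-cluster
  sum of squared Euclidean distances (WCSS), with best-of-``n_init``
  restarts and a silhouette-based selector for the number of clusters.

Non-expressers enter clustering at the expression floor ``-B``; a cell
that fails to amplify a cluster's marker genes is thereby maximally
distant from that cluster in those coordinates, which is the intended
behavior for presence/absence structure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.utils.validation import check_is_fitted

from .normalize import ExpressionMatrix


@dataclass
class Dendrogram:
    """Agglomerative merge tree (scipy linkage encoding).

    ``merges`` is the (n-1) x 4 scipy linkage matrix: children ids, merge
    height (Euclidean), subtree size.  Complete linkage guarantees heights
    are non-decreasing along any root path.
    """

    merges: np.ndarray
    leaf_order: np.ndarray
    axis: str = "cells"

    @property
    def n_leaves(self) -> int:
        return self.merges.shape[0] + 1


@dataclass
class ClusterModel:
    """A fitted k-means partition of cells.

    ``assignment`` uses 1-based labels (cluster "1".."k", matching how
    subpopulations are referred to in figures).  ``centroids`` are cluster
    means in log2 expression units.  ``within_q95`` is the 95th percentile
    of member-to-centroid distances, a scale-aware yardstick used as the
    default match radius when comparing models across groups.
    """

    k: int
    assignment: np.ndarray
    centroids: np.ndarray
    wcss: float
    seed: int
    n_init: int
    genes: list
    bound: float
    cells: list = field(default_factory=list)
    leaf_order: np.ndarray | None = None
    within_q95: float = float("nan")

    @property
    def sizes(self) -> np.ndarray:
        """Member count per cluster, index 0 = cluster 1."""
        return np.bincount(self.assignment - 1, minlength=self.k)

    @property
    def abundances(self) -> np.ndarray:
        return self.sizes / self.sizes.sum()

    def members(self, cluster_id: int) -> np.ndarray:
        """Boolean mask over cells for a 1-based cluster id."""
        return self.assignment == cluster_id

    def to_json(self, path) -> None:
        d = asdict(self)
        for key in ("assignment", "centroids", "leaf_order"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        with open(path) as fh:
            d = json.load(fh)
        d["assignment"] = np.asarray(d["assignment"], dtype=int)
        d["centroids"] = np.asarray(d["centroids"], dtype=float)
        if d.get("leaf_order") is not None:
            d["leaf_order"] = np.asarray(d["leaf_order"], dtype=int)
        return cls(**d)


class KMeansSubpopulations(ClusterMixin, BaseEstimator):
    """k-means cell partitioning with deterministic multi-restart search.

    A thin estimator over Lloyd's algorithm with k-means++ seeding: the
    best of ``n_init`` restarts by WCSS is kept, so the fit is reproducible
    given ``(random_state, n_init, input order)`` and WCSS is non-increasing
    in ``n_init``.  Empty clusters are re-seeded from the point farthest
    from its centroid.

    Parameters
    ----------
    n_clusters : int
    n_init : int, default 50
    random_state : int, default 0

    Attributes
    ----------
    labels_ : ndarray of int, 0-based cluster labels
    cluster_centers_ : ndarray (k, n_genes)
    inertia_ : float, the minimized WCSS
    """

    def __init__(self, n_clusters: int = 4, n_init: int = 50, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("expression matrix must be finite")
        if self.n_clusters > X.shape[0]:
            raise ValueError(
                f"k={self.n_clusters} exceeds the {X.shape[0]} available cells"
            )
        km = KMeans(
            n_clusters=self.n_clusters,
            n_init=self.n_init,
            random_state=self.random_state,
            algorithm="lloyd",
        ).fit(X)
        self.labels_ = km.labels_
        self.cluster_centers_ = km.cluster_centers_
        self.inertia_ = float(km.inertia_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        d = np.linalg.norm(X[:, None, :] - self.cluster_centers_[None], axis=2)
        # ties resolved toward the lowest cluster index
        return np.argmin(d, axis=1)


def _axis_data(e: ExpressionMatrix, axis: str) -> np.ndarray:
    if axis == "cells":
        return e.expr
    if axis == "genes":
        return e.expr.T
    raise ValueError(f"axis must be 'cells' or 'genes', got {axis!r}")


def hierarchical_clustergram(e: ExpressionMatrix, axis: str = "cells") -> Dendrogram:
    """Complete-linkage dendrogram on Euclidean distances over one axis."""
    X = _axis_data(e, axis)
    if X.shape[0] < 2:
        raise ValueError(f"need at least 2 items on axis {axis!r}")
    Z = linkage(X, method="complete", metric="euclidean")
    return Dendrogram(merges=Z, leaf_order=leaves_list(Z), axis=axis)


def kmeans_partition(
    e: ExpressionMatrix, k: int, seed: int = 0, n_init: int = 50
) -> ClusterModel:
    """Partition cells into ``k`` subpopulations minimizing WCSS."""
    est = KMeansSubpopulations(n_clusters=k, n_init=n_init, random_state=seed).fit(
        e.expr
    )
    assignment = est.labels_ + 1
    dists = np.linalg.norm(e.expr - est.cluster_centers_[est.labels_], axis=1)
    model = ClusterModel(
        k=k,
        assignment=assignment,
        centroids=est.cluster_centers_,
        wcss=est.inertia_,
        seed=seed,
        n_init=n_init,
        genes=list(e.genes),
        bound=e.bound,
        cells=list(e.cells),
        within_q95=float(np.percentile(dists, 95)) if len(dists) else float("nan"),
    )
    model.leaf_order = subgroup_order(e, model)
    return model


def select_k(
    e: ExpressionMatrix,
    k_range=range(2, 9),
    seed: int = 0,
    n_init: int = 50,
    no_structure_silhouette: float = 0.25,
):
    """Choose k by mean silhouette width over ``k_range``.

    Returns ``(k, diagnostics)`` where diagnostics is a DataFrame with one
    row per candidate k (columns ``k``, ``wcss``, ``silhouette``) plus a
    ``no_structure`` attribute flag: True when no candidate reaches a mean
    silhouette of ``no_structure_silhouette``, i.e. the data look like one
    homogeneous cloud.  Degenerate input (all cells identical) returns k=1
    with a warning and an empty table.
    """
    ks = [int(k) for k in k_range]
    if any(k < 2 or k > e.n_cells - 1 for k in ks):
        raise ValueError("k_range must lie within [2, n_cells - 1]")
    if np.allclose(e.expr, e.expr[0]):
        warnings.warn("all cells identical; no partition possible", UserWarning)
        diag = pd.DataFrame(columns=["k", "wcss", "silhouette"])
        diag.attrs["no_structure"] = True
        return 1, diag
    rows = []
    for k in ks:
        est = KMeansSubpopulations(n_clusters=k, n_init=n_init, random_state=seed).fit(
            e.expr
        )
        sil = silhouette_score(e.expr, est.labels_)
        rows.append({"k": k, "wcss": est.inertia_, "silhouette": sil})
    diag = pd.DataFrame(rows)
    best = diag.loc[diag["silhouette"].idxmax()]
    no_structure = bool(diag["silhouette"].max() < no_structure_silhouette)
    diag.attrs["no_structure"] = no_structure
    if no_structure:
        warnings.warn(
            "no cluster structure detected (max silhouette "
            f"{diag['silhouette'].max():.3f} < {no_structure_silhouette})",
            UserWarning,
        )
    return int(best["k"]), diag


def _complete_leaf_order(X: np.ndarray) -> np.ndarray:
    if X.shape[0] < 2:
        return np.arange(X.shape[0])
    return leaves_list(linkage(X, method="complete", metric="euclidean"))


def subgroup_order(e: ExpressionMatrix, model: ClusterModel) -> np.ndarray:
    """Heatmap row order: clusters as contiguous blocks, tree order within.

    Cells within each k-means cluster are ordered by their complete-linkage
    leaf order; the cluster blocks themselves are concatenated in the leaf
    order of a dendrogram over the centroids.  The result is a permutation
    of all cell indices.
    """
    cluster_seq = (
        _complete_leaf_order(model.centroids) if model.k > 1 else np.array([0])
    )
    order = []
    for c in cluster_seq:
        idx = np.flatnonzero(model.assignment == c + 1)
        order.extend(idx[_complete_leaf_order(e.expr[idx])])
    return np.asarray(order, dtype=int)
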