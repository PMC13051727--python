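"""Cross-group cluster matching and absence detection.

When two experimental groups are clustered independently, their clusters
carry arbitrary labels; biological claims like "subpopulation 2 is absent
in the knockout" require first deciding which cluster in group B, if any,
corresponds to each cluster in group A.  Matching is done in centroid
space on the shared normalized gene panel: an exact one-to-one assignment
(Hungarian algorithm) minimizes the total centroid Euclidean distance,
pairs farther apart than ``max_dist`` are broken, and each group-A cluster
is then called

* ``present``  — matched, relative abundance in B at least half that in A;
* ``depleted`` — matched but abundance ratio B/A below 0.5, or B abundance
  at or below the minority floor;
* ``absent``   — unmatched, or matched to a B cluster below the minority
  floor (strict inequality).

The default ``max_dist`` is the 95th percentile of group A's member-to-
centroid distances — a scale-aware radius: a true counterpart should sit
no farther from A's centroid than A's own peripheral members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cluster import ClusterModel


@dataclass
class ClusterMatch:
    """One-to-one correspondence between two groups' cluster models."""

    pairs: list  # (a_cluster_1based, b_cluster_1based, centroid_distance)
    unmatched_a: list
    unmatched_b: list
    abundance_a: np.ndarray  # per A cluster, sums to 1
    abundance_b: np.ndarray  # per B cluster, sums to 1
    max_dist: float
    total_cost: float = field(default=float("nan"))

    def matched_b_for(self, a_cluster: int):
        for a, b, d in self.pairs:
            if a == a_cluster:
                return b, d
        return None, float("nan")


def match_clusters(
    modelA: ClusterModel, modelB: ClusterModel, max_dist: float | None = None
) -> ClusterMatch:
    """Optimally pair clusters of two models by centroid distance.

    Both models must share the gene panel and normalization bound.  With
    unequal k, ``min(kA, kB)`` pairs are formed; leftover clusters are
    unmatched.  Matched pairs with distance greater than ``max_dist`` are
    broken and reported unmatched on both sides.
    """
    if list(modelA.genes) != list(modelB.genes):
        raise ValueError("cluster models were built on different gene panels")
    if modelA.bound != modelB.bound:
        raise ValueError(
            f"normalization bounds differ ({modelA.bound} vs {modelB.bound})"
        )
    if max_dist is None:
        max_dist = modelA.within_q95
    dist = np.linalg.norm(
        modelA.centroids[:, None, :] - modelB.centroids[None, :, :], axis=2
    )
    rows, cols = linear_sum_assignment(dist)
    pairs, unmatched_a, unmatched_b = [], [], []
    matched_a, matched_b = set(), set()
    total = 0.0
    for i, j in zip(rows, cols):
        d = float(dist[i, j])
        if d > max_dist:
            continue
        pairs.append((int(i) + 1, int(j) + 1, d))
        matched_a.add(int(i))
        matched_b.add(int(j))
        total += d
    unmatched_a = [i + 1 for i in range(modelA.k) if i not in matched_a]
    unmatched_b = [j + 1 for j in range(modelB.k) if j not in matched_b]
    return ClusterMatch(
        pairs=pairs,
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
        abundance_a=modelA.abundances,
        abundance_b=modelB.abundances,
        max_dist=float(max_dist),
        total_cost=total,
    )


def absence_report(
    match: ClusterMatch,
    minority_floor: float = 0.02,
    depletion_ratio: float = 0.5,
) -> pd.DataFrame:
    """Call each group-A cluster present, depleted, or absent in group B.

    Tie rule at the floor: a matched B abundance exactly equal to
    ``minority_floor`` is ``depleted``, not ``absent`` (absence requires
    strictly less).
    """
    rows = []
    for a in range(1, len(match.abundance_a) + 1):
        ab_a = float(match.abundance_a[a - 1])
        b, d = match.matched_b_for(a)
        if b is None:
            status, ab_b, ratio = "absent", 0.0, 0.0
        else:
            ab_b = float(match.abundance_b[b - 1])
            ratio = ab_b / ab_a if ab_a > 0 else float("inf")
            if ab_b < minority_floor:
                status = "absent"
            elif ratio < depletion_ratio or ab_b == minority_floor:
                status = "depleted"
            else:
                status = "present"
        rows.append(
            {
                "cluster_a": a,
                "matched_b": b if b is not None else pd.NA,
                "centroid_distance": d,
                "abundance_a": ab_a,
                "abundance_b": ab_b,
                "abundance_ratio": ratio,
                "status": status,
            }
        )
    return pd.DataFrame(rows)
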