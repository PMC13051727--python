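"""End-to-end per-group analysis.

Glue for the common workflow: normalize the pooled Ct matrix once, then
cluster each experimental group independently (optionally selecting k per
group by silhouette), match the two sets of clusters in centroid space,
and report which subpopulations are present, depleted, or absent in the
second group.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cluster import ClusterModel, kmeans_partition, select_k
from .crossgroup import ClusterMatch, absence_report, match_clusters
from .ct import CtMatrix
from .normalize import ExpressionMatrix, pooled_median_normalize


@dataclass
class GroupComparison:
    expression: ExpressionMatrix
    model_a: ClusterModel
    model_b: ClusterModel
    match: ClusterMatch
    report: pd.DataFrame
    diagnostics: dict


def subset_expression(e: ExpressionMatrix, mask) -> ExpressionMatrix:
    """Row-subset an expression matrix (used to split groups)."""
    import numpy as np

    mask = np.asarray(mask)
    idx = np.flatnonzero(mask) if mask.dtype == bool else mask
    return ExpressionMatrix(
        cells=[e.cells[i] for i in idx],
        genes=list(e.genes),
        expr=e.expr[idx],
        nonexpresser=e.nonexpresser[idx],
        bound=e.bound,
        meta=e.meta.iloc[idx],
    )


def analyze_groups(
    m: CtMatrix,
    group_a: str,
    group_b: str,
    k_a: int | None = None,
    k_b: int | None = None,
    k_range=range(2, 9),
    bound: float = 5.0,
    seed: int = 0,
    n_init: int = 50,
) -> GroupComparison:
    """Normalize, cluster each group, match clusters, and call absences.

    ``k_a`` / ``k_b`` fix the cluster counts; leaving them None selects k
    per group by mean silhouette over ``k_range``.
    """
    e = pooled_median_normalize(m, bound=bound)
    diagnostics = {}
    models = {}
    for label, k_fixed in ((group_a, k_a), (group_b, k_b)):
        sub = subset_expression(e, e.group_mask(label))
        if k_fixed is None:
            k_fixed, diag = select_k(sub, k_range=k_range, seed=seed, n_init=n_init)
            diagnostics[label] = diag
        models[label] = kmeans_partition(sub, k=k_fixed, seed=seed, n_init=n_init)
    match = match_clusters(models[group_a], models[group_b])
    report = absence_report(match)
    return GroupComparison(
        expression=e,
        model_a=models[group_a],
        model_b=models[group_b],
        match=match,
        report=report,
        diagnostics=diagnostics,
    )
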