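"""Kolmogorov–Smirnov differential expression with Bonferroni control.

Per-gene expression distributions are compared between two sets of cells
with the nonparametric two-sample K–S test: D is the largest vertical gap
between the two empirical CDFs, and the p-value comes from the asymptotic
Kolmogorov distribution at the standard effective sample size
``sqrt(n*m/(n+m))``.  Because many cells sit tied at the expression floor,
a distribution-free test on the ECDF (which handles ties by construction)
is the appropriate choice over, say, a t-test.

Family-wise error across the gene panel is controlled by Bonferroni:
``p_bonf = min(1, m * p_raw)`` with ``m`` the number of genes in the
comparison family, and a strict cutoff ``p_bonf < alpha``.

Two comparison designs are provided:

* ``cluster_vs_rest`` — each subpopulation against all remaining cells,
  the design used to derive per-cluster marker ("seed") gene panels;
* ``group_vs_group`` — one experimental group against the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterModel
from .normalize import ExpressionMatrix


@dataclass
class DiffResult:
    """Per-gene K–S differential test results for one comparison family."""

    table: pd.DataFrame  # gene, ks_D, p_raw, p_bonf, significant, direction
    alpha: float
    comparison: str
    m: int  # Bonferroni multiplicity actually applied

    @property
    def significant_genes(self) -> list:
        return self.table.loc[self.table["significant"], "gene"].tolist()

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample K–S statistic and asymptotic p-value.

    ``D = sup_t |ECDF_x(t) - ECDF_y(t)|``; ties (e.g. values at the
    expression floor) are handled directly by the ECDF definition.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if min(x.size, y.size) < 5:
        import warnings

        warnings.warn(
            f"K-S test with n={min(x.size, y.size)} < 5 has little power",
            UserWarning,
            stacklevel=2,
        )
    res = stats.ks_2samp(x, y, method="asymp")
    # the asymptotic sf underflows to 0 for extreme D; keep p in (0, 1]
    return float(res.statistic), max(float(res.pvalue), np.finfo(float).tiny)


def _ks_panel(e: ExpressionMatrix, focal, reference, alpha, comparison, m=None):
    focal = np.asarray(focal, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    n_genes = e.n_genes
    m = n_genes if m is None else int(m)
    rows = []
    for j, gene in enumerate(e.genes):
        xf = e.expr[focal, j]
        xr = e.expr[reference, j]
        res = stats.ks_2samp(xf, xr, method="asymp")
        d = float(res.statistic)
        p = max(float(res.pvalue), np.finfo(float).tiny)
        p_bonf = min(1.0, m * p)
        rows.append(
            {
                "gene": gene,
                "ks_D": d,
                "p_raw": p,
                "p_bonf": p_bonf,
                "significant": p_bonf < alpha,
                "direction": int(np.sign(np.median(xf) - np.median(xr))),
            }
        )
    return DiffResult(pd.DataFrame(rows), alpha=alpha, comparison=comparison, m=m)


def cluster_vs_rest(
    e: ExpressionMatrix,
    model: ClusterModel,
    cluster_id: int,
    alpha: float = 0.05,
    multiplicity: str = "genes",
) -> DiffResult:
    """Test each gene in one subpopulation against all remaining cells.

    ``multiplicity='genes'`` (default) corrects over the gene panel;
    ``'genes_x_clusters'`` corrects over genes times the number of
    clusters, for callers running every cluster as one family.
    """
    focal = model.members(cluster_id)
    rest = ~focal
    if not focal.any():
        raise ValueError(f"cluster {cluster_id} is empty")
    if not rest.any():
        raise ValueError(f"cluster {cluster_id} covers all cells; no rest to compare")
    if multiplicity == "genes":
        m = e.n_genes
    elif multiplicity == "genes_x_clusters":
        m = e.n_genes * model.k
    else:
        raise ValueError(f"unknown multiplicity {multiplicity!r}")
    return _ks_panel(
        e, focal, rest, alpha, comparison=f"cluster-{cluster_id}-vs-rest", m=m
    )


def group_vs_group(
    e: ExpressionMatrix, groups=None, alpha: float = 0.05, focal=None
) -> DiffResult:
    """Test each gene between the two experimental groups.

    ``groups`` is a per-cell label vector (defaults to the matrix's group
    metadata); exactly two distinct labels are required — with more, run
    pairwise comparisons explicitly.  Direction is the sign of the focal
    minus reference median; the focal group is the lexicographically first
    label unless ``focal`` names one explicitly, so relabeling the groups
    flips every direction while leaving D and p untouched.
    """
    labels = np.asarray(e.groups if groups is None else groups)
    uniq = sorted(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(
            f"expected exactly 2 group labels, got {list(uniq)}; "
            "run pairwise comparisons for >2 groups"
        )
    a, b = uniq
    if focal is not None:
        if focal not in uniq:
            raise ValueError(f"focal label {focal!r} not among {uniq}")
        if focal == b:
            a, b = b, a
    return _ks_panel(
        e, labels == a, labels == b, alpha, comparison=f"group-{a}-vs-{b}"
    )


def export_seed_genes(r: DiffResult, path) -> None:
    """Write significant genes (the pathway-analysis seed list) to CSV."""
    cols = ["gene", "ks_D", "p_bonf", "direction"]
    r.table.loc[r.table["significant"], cols].to_csv(path, index=False)


def read_seed_genes(path) -> pd.DataFrame:
    return pd.read_csv(path)
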