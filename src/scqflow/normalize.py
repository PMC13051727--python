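"""Pooled-median Ct normalization with bounded log2 expression.

A Ct value is the PCR cycle at which fluorescence crosses detection, so one
cycle is one doubling: a cell sitting one cycle *below* a gene's typical Ct
has roughly twice the transcript.  Expression is therefore reported as

    expr[c, g] = clip( median_g(Ct) - Ct[c, g], -B, +B )

where ``median_g`` is taken over all cells with a successful reaction,
pooled across every experimental group so both groups share one reference
point per gene.  The result is a log2 fold change relative to the pooled
median: positive means more transcript than the typical cell, and the
symmetric bound ``B`` (default 5 cycles, i.e. a 32-fold change) caps the
dynamic range.  Reactions that failed to amplify ("non-expressers") carry
no Ct information beyond "below detection"; they are excluded from the
median and assigned the floor ``-B``.

The transformation is exposed both as a scikit-learn transformer over plain
(cells x genes) arrays with NaN marking failure, and as
:func:`pooled_median_normalize` over :class:`~scqflow.ct.CtMatrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .ct import CtMatrix


@dataclass
class ExpressionMatrix:
    """Bounded log2 expression relative to pooled per-gene medians."""

    cells: list
    genes: list
    expr: np.ndarray
    nonexpresser: np.ndarray
    bound: float
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.expr = np.asarray(self.expr, dtype=float)
        self.nonexpresser = np.asarray(self.nonexpresser, dtype=bool)
        if self.meta is None:
            self.meta = pd.DataFrame(index=pd.Index(self.cells, name="cell"))

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def groups(self) -> pd.Series:
        return self.meta["group"]

    def group_mask(self, label: str) -> np.ndarray:
        return (self.meta["group"] == label).to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.expr, index=self.cells, columns=self.genes)


class PooledMedianNormalizer(TransformerMixin, BaseEstimator):
    """Median-center Ct values per gene and clip to ``[-bound, +bound]``.

    Works on 2D float arrays of shape (cells, genes) with NaN marking
    failed amplification.  ``fit`` learns the per-gene pooled median over
    non-NaN entries; ``transform`` returns ``clip(median - ct, -B, +B)``
    with NaN entries floored to ``-bound``.

    Parameters
    ----------
    bound : float, default 5.0
        Absolute bound in cycle thresholds (log2 units).  ``bound=5``
        corresponds to a maximal 32-fold change.

    Attributes
    ----------
    gene_medians_ : ndarray of shape (n_genes,)
        Pooled median Ct per gene (NaN for all-failed genes).
    all_failed_genes_ : ndarray of int
        Column indices with no successful reaction; carried at the floor.
    """

    def __init__(self, bound: float = 5.0):
        self.bound = bound

    def fit(self, X, y=None):
        if self.bound <= 0:
            raise ValueError(f"bound must be positive, got {self.bound}")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2D (cells x genes) array")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            self.gene_medians_ = np.nanmedian(X, axis=0)
        self.all_failed_genes_ = np.flatnonzero(np.isnan(self.gene_medians_))
        if len(self.all_failed_genes_):
            warnings.warn(
                f"{len(self.all_failed_genes_)} gene(s) had no successful "
                "amplification; retained at the floor",
                UserWarning,
                stacklevel=2,
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        expr = self.gene_medians_[np.newaxis, :] - X
        expr = np.clip(expr, -self.bound, self.bound)
        expr[np.isnan(expr)] = -self.bound
        return expr


def pooled_median_normalize(
    m: CtMatrix, bound: float = 5.0, per_group: bool = False
) -> ExpressionMatrix:
    """Normalize a :class:`CtMatrix` to bounded log2 relative expression.

    Parameters
    ----------
    m : CtMatrix
    bound : float, default 5.0
    per_group : bool, default False
        If True, medians are pooled within each group label instead of
        across all cells.  The default (global pooling) gives both groups
        a common per-gene reference.
    """
    X = np.where(m.failed, np.nan, m.ct)
    if per_group:
        expr = np.empty_like(X)
        for label in pd.unique(m.meta["group"]):
            sel = m.group_mask(str(label))
            expr[sel] = PooledMedianNormalizer(bound).fit_transform(X[sel])
    else:
        expr = PooledMedianNormalizer(bound).fit_transform(X)
    return ExpressionMatrix(
        cells=m.cells,
        genes=m.genes,
        expr=expr,
        nonexpresser=m.failed.copy(),
        bound=float(bound),
        meta=m.meta,
    )


def fold_change_bound(bound: float) -> float:
    """Maximal linear fold change representable under a log2 bound.

    A bound of ``B`` cycle thresholds caps expression at ``2**B``-fold
    above or below the pooled median (5 cycles -> 32-fold; 0 -> identity).
    """
    if bound < 0:
        raise ValueError(f"bound must be non-negative, got {bound}")
    return float(2.0**bound)


def nonexpresser_fraction(e: ExpressionMatrix, gene, subset=None) -> float:
    """Fraction of cells in ``subset`` whose reaction for ``gene`` failed.

    ``subset`` is a boolean mask or index array over cells; None means all
    cells.  Mirrors per-cluster "fraction failed to amplify" bars.
    """
    if gene not in e.genes:
        raise KeyError(f"unknown gene {gene!r}")
    j = e.genes.index(gene)
    col = e.nonexpresser[:, j]
    if subset is not None:
        sel = np.asarray(subset)
        if sel.size == 0:
            raise ValueError("empty cell subset")
        col = col[sel.astype(int) if sel.dtype != bool else sel]
    if col.size == 0:
        raise ValueError("empty cell subset")
    return float(np.mean(col))
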