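"""Ct table input/output.

Raw single-cell qPCR data arrives as cycle-threshold (Ct) tables from
microfluidic dynamic arrays: one Ct value per (cell, gene) reaction, with
some reactions failing to amplify.  Failed reactions are encoded in vendor
exports by sentinel tokens (``999`` being the Fluidigm convention, empty
cells or ``No Call`` in hand-edited sheets); they are carried here as an
explicit boolean mask rather than a magic value, so no downstream statistic
can accidentally treat a sentinel as a measurement.

Two CSV dialects are supported and round-trip losslessly:

``wide``
    one row per cell: ``cell,plate,well,group,<gene1>,<gene2>,...``
``long``
    one row per (cell, gene) reaction: ``cell,gene,ct`` with cell metadata
    repeated in ``plate,well,group`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_NA_TOKENS = ("", "NA", "No Call", "999")

_META_COLS = ("plate", "well", "group")


@dataclass
class CtMatrix:
    """Cycle-threshold matrix with a failed-amplification mask.

    Parameters
    ----------
    cells : list of str
        Unique cell identifiers, in file/generation order.
    genes : list of str
        Unique gene symbols, in file/generation order.
    ct : ndarray of shape (n_cells, n_genes)
        Cycle-threshold values.  Entries where ``failed`` is True are
        ignored by all downstream math (the stored number is arbitrary;
        NaN by convention).
    failed : ndarray of bool, same shape
        True where the reaction failed to amplify.
    meta : DataFrame indexed by cell id
        Columns ``plate``, ``well``, ``group``.
    """

    cells: list
    genes: list
    ct: np.ndarray
    failed: np.ndarray
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.cells = list(self.cells)
        self.genes = list(self.genes)
        self.ct = np.asarray(self.ct, dtype=float)
        self.failed = np.asarray(self.failed, dtype=bool)
        if self.ct.shape != (len(self.cells), len(self.genes)):
            raise ValueError(
                f"ct shape {self.ct.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        if self.failed.shape != self.ct.shape:
            raise ValueError("failed mask shape differs from ct shape")
        for name, ids in (("cell", self.cells), ("gene", self.genes)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dupes):
                raise ValueError(f"duplicate {name} id: {dupes[0]!r}")
        if self.meta is None:
            self.meta = pd.DataFrame(
                {c: [""] * len(self.cells) for c in _META_COLS},
                index=pd.Index(self.cells, name="cell"),
            )
        else:
            self.meta = self.meta.copy()
            self.meta.index = pd.Index(self.cells, name="cell")
            for c in _META_COLS:
                if c not in self.meta.columns:
                    self.meta[c] = ""
            self.meta = self.meta[list(_META_COLS)].astype(str)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def groups(self) -> pd.Series:
        """Group label per cell (e.g. ``"WT"`` / ``"eKO"``)."""
        return self.meta["group"]

    def group_mask(self, label: str) -> np.ndarray:
        return (self.meta["group"] == label).to_numpy()


def _parse_value(raw, na_tokens, where):
    s = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
    if s in na_tokens:
        return np.nan, True
    try:
        return float(s), False
    except ValueError:
        raise ValueError(f"non-numeric non-NA token {s!r} at {where}") from None


def read_ct_csv(path, dialect: str = "wide", na_tokens=DEFAULT_NA_TOKENS) -> CtMatrix:
    """Read a Ct table from CSV.

    ``na_tokens`` are compared after stripping whitespace; a matching token
    (or an empty / missing field) marks the reaction failed.  Any other
    non-numeric value is a hard error naming the offending position.
    """
    na_tokens = set(str(t) for t in na_tokens)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect == "wide":
        return _from_wide(df, na_tokens)
    if dialect == "long":
        return _from_long(df, na_tokens)
    raise ValueError(f"unknown dialect {dialect!r}")


def _from_wide(df: pd.DataFrame, na_tokens) -> CtMatrix:
    cell_col = df.columns[0]
    meta_cols = [c for c in df.columns[1:4] if c in _META_COLS]
    gene_cols = [c for c in df.columns[1:] if c not in _META_COLS]
    cells = df[cell_col].tolist()
    ct = np.full((len(cells), len(gene_cols)), np.nan)
    failed = np.zeros_like(ct, dtype=bool)
    for j, g in enumerate(gene_cols):
        for i, raw in enumerate(df[g]):
            ct[i, j], failed[i, j] = _parse_value(
                raw, na_tokens, f"row {i + 2}, column {g!r}"
            )
    meta = pd.DataFrame(
        {c: (df[c].tolist() if c in meta_cols else [""] * len(cells)) for c in _META_COLS}
    )
    return CtMatrix(cells, gene_cols, ct, failed, meta)


def _from_long(df: pd.DataFrame, na_tokens) -> CtMatrix:
    required = {"cell", "gene", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"long dialect needs columns {sorted(required)}")
    cells = list(dict.fromkeys(df["cell"]))
    genes = list(dict.fromkeys(df["gene"]))
    ci = {c: i for i, c in enumerate(cells)}
    gi = {g: i for i, g in enumerate(genes)}
    ct = np.full((len(cells), len(genes)), np.nan)
    failed = np.ones_like(ct, dtype=bool)  # absent (cell,gene) rows = failed
    seen = np.zeros_like(failed)
    meta = {c: {} for c in _META_COLS}
    for idx, row in df.iterrows():
        i, j = ci[row["cell"]], gi[row["gene"]]
        if seen[i, j]:
            raise ValueError(
                f"duplicate (cell, gene) pair ({row['cell']!r}, {row['gene']!r})"
            )
        seen[i, j] = True
        ct[i, j], failed[i, j] = _parse_value(
            row["ct"], na_tokens, f"row {idx + 2}, column 'ct'"
        )
        for c in _META_COLS:
            if c in df.columns:
                meta[c][row["cell"]] = row[c]
    meta_df = pd.DataFrame(
        {c: [meta[c].get(cell, "") for cell in cells] for c in _META_COLS}
    )
    return CtMatrix(cells, genes, ct, failed, meta_df)


def write_ct_csv(m: CtMatrix, path, dialect: str = "wide", na_token: str = "999") -> None:
    """Write a Ct table; ``read_ct_csv`` on the result round-trips exactly.

    Failed entries are written as ``na_token``.  Long dialect emits one row
    per non-absent reaction (failed reactions are written with the token so
    the mask survives the round-trip).
    """
    if dialect == "wide":
        data = {m.meta.index.name or "cell": m.cells}
        for c in _META_COLS:
            data[c] = m.meta[c].tolist()
        for j, g in enumerate(m.genes):
            col = [
                na_token if m.failed[i, j] else repr(float(m.ct[i, j]))
                for i in range(m.n_cells)
            ]
            data[g] = col
        pd.DataFrame(data).to_csv(path, index=False)
    elif dialect == "long":
        rows = []
        for i, cell in enumerate(m.cells):
            pl, we, gr = (m.meta.iloc[i][c] for c in _META_COLS)
            for j, g in enumerate(m.genes):
                val = na_token if m.failed[i, j] else repr(float(m.ct[i, j]))
                rows.append((cell, g, val, pl, we, gr))
        pd.DataFrame(
            rows, columns=["cell", "gene", "ct", "plate", "well", "group"]
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
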