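import numpy as np
import pandas as pd
import pytest

from scqflow import CtMatrix, ExpressionMatrix


@pytest.fixture
def small_ct():
    """4 cells x 3 genes with two failed reactions."""
    ct = np.array(
        [
            [20.0, 30.0, 25.0],
            [21.0, 31.0, np.nan],
            [22.0, 29.0, 26.0],
            [23.0, np.nan, 24.0],
        ]
    )
    failed = np.isnan(ct)
    meta = pd.DataFrame(
        {
            "plate": ["P1"] * 4,
            "well": [f"W{i}" for i in range(1, 5)],
            "group": ["WT", "WT", "eKO", "eKO"],
        }
    )
    return CtMatrix(["c1", "c2", "c3", "c4"], ["g1", "g2", "g3"], ct, failed, meta)


def make_expression(expr, bound=5.0, groups=None):
    """Build an ExpressionMatrix directly from a value array."""
    expr = np.asarray(expr, dtype=float)
    n, p = expr.shape
    cells = [f"c{i}" for i in range(n)]
    meta = None
    if groups is not None:
        meta = pd.DataFrame({"plate": "", "well": "", "group": list(groups)})
        meta.index = pd.Index(cells, name="cell")
    return ExpressionMatrix(
        cells=cells,
        genes=[f"g{j}" for j in range(p)],
        expr=expr,
        nonexpresser=np.zeros_like(expr, dtype=bool),
        bound=bound,
        meta=meta,
    )
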