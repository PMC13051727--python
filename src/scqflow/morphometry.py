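"""Caliper tumor morphometry, wound-closure curves, and relative expression.

Small, exact arithmetic helpers for the bench-side measurements that
accompany the single-cell work: ellipsoid-style caliper tumor volume
``V = 0.5 * L * W * H`` (cm^3) and density ``D = M / V`` (g/cm^3); wound
area time series reduced to fraction-open curves and a closure day; and
reference-gene-normalized qRT-PCR relative expression ``2**-dCt``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def tumor_volume(L: float, W: float, H: float) -> float:
    """Caliper tumor volume ``0.5 * L * W * H`` (dimensions in cm -> cm^3)."""
    if L < 0 or W < 0 or H < 0:
        raise ValueError("caliper dimensions must be non-negative")
    return 0.5 * L * W * H


def tumor_density(mass: float, volume: float) -> float:
    """Tumor density ``mass / volume`` in g/cm^3; volume must be positive."""
    if volume <= 0:
        raise ValueError("volume must be positive to compute density")
    return mass / volume


def tumor_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add ``volume`` (and ``density`` where mass is present) columns.

    Expects columns ``L``, ``W``, ``H`` in cm and optionally ``mass`` in g.
    """
    out = df.copy()
    out["volume"] = [
        tumor_volume(r.L, r.W, r.H) for r in df.itertuples()
    ]
    if "mass" in df.columns:
        out["density"] = [
            tumor_density(m, v) if pd.notna(m) and v > 0 else np.nan
            for m, v in zip(out["mass"], out["volume"])
        ]
    return out


@dataclass
class WoundSeries:
    """Fraction-open curve for one wound."""

    wound_id: str
    days: np.ndarray
    area: np.ndarray  # mm^2
    fraction_open: np.ndarray
    closure_day: int | None  # first day with (effectively) zero area


def wound_closure(measurements, wound_id: str = "", epsilon: float = 0.0) -> WoundSeries:
    """Reduce (day, area) pairs to a fraction-open curve and closure day.

    Day 0 must be present with positive area; ``fraction_open`` is area
    relative to day 0 and the closure day is the first day whose area is
    at or below ``epsilon`` (default: strictly zero area closes).
    """
    pairs = sorted((int(d), float(a)) for d, a in measurements)
    days = np.array([d for d, _ in pairs])
    area = np.array([a for _, a in pairs])
    if len(days) == 0 or days[0] != 0:
        raise ValueError("wound series must start at day 0")
    if area[0] <= 0:
        raise ValueError("day-0 wound area must be positive")
    fraction = area / area[0]
    closed = np.flatnonzero(area <= epsilon)
    closure_day = int(days[closed[0]]) if len(closed) else None
    return WoundSeries(wound_id, days, area, fraction, closure_day)


def relative_expression(
    ct_target: float, ct_reference: float, calibrator_delta: float = 0.0
) -> float:
    """Reference-gene-normalized expression ``2**-(dCt - calibrator_delta)``.

    ``dCt = ct_target - ct_reference`` (e.g. target vs B2m); with a
    calibrator delta this is the ddCt method, otherwise plain ``2**-dCt``
    relative values.  Strictly decreasing in ``ct_target`` and increasing
    in ``ct_reference``.
    """
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** -((ct_target - ct_reference) - calibrator_delta))
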