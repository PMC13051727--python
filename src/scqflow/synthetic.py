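"""Synthetic data with the statistical structure the pipeline assumes.

Every analysis stage is testable without any instrument export: this
module emits Ct matrices with planted subpopulations, ground-truthed
fluorescence images, and caliper tumor tables, all reproducible from a
single seed.

The default Ct design mirrors a four-plate sorted-cell experiment: 384
cells in four 96-well plates (two plates per group), a 96-gene panel, and
four latent subpopulations with distinct mean Ct profiles.  Each
subpopulation owns a block of marker genes whose mean Ct sits
``marker_shift`` cycles below the 25-cycle background (lower Ct = more
transcript), with Gaussian cycle noise (sd 1.0) and independent per-
reaction dropout emulating failed amplification.  Group composition
mirrors the cross-group comparison of interest: cluster 2 is entirely
absent from the second group and cluster 3 is depleted there, while two
subpopulations are preserved — the presence/absence structure the
cross-group matcher is meant to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct import CtMatrix

BACKGROUND_CT = 25.0


@dataclass
class ClusterSpec:
    """One latent subpopulation: its markers, noise, and dropout."""

    name: str
    proportions: dict  # group label -> mixing proportion within that group
    marker_genes: list  # gene indices whose mean Ct is shifted down
    ct_sd: float = 1.0
    dropout: float = 0.15  # per-reaction failure probability


@dataclass
class SyntheticSpec:
    """Design of a synthetic single-cell qPCR experiment."""

    n_plates: int = 4
    wells_per_plate: int = 96
    n_genes: int = 96
    groups: tuple = ("WT", "eKO")
    marker_shift: float = 4.0  # cycles below background for marker genes
    background_ct: float = BACKGROUND_CT
    clusters: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not self.clusters:
            self.clusters = default_clusters(
                self.groups, self.n_genes, markers_per_cluster=8
            )
        for g in self.groups:
            total = sum(c.proportions.get(g, 0.0) for c in self.clusters)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"cluster proportions for group {g!r} sum to {total}, not 1"
                )

    @property
    def n_cells(self) -> int:
        return self.n_plates * self.wells_per_plate


def default_clusters(groups=("WT", "eKO"), n_genes=96, markers_per_cluster=8):
    """Four subpopulations: one absent and one depleted in the second group."""
    a, b = groups
    props = [
        {a: 0.30, b: 0.45},
        {a: 0.25, b: 0.00},  # absent in group B
        {a: 0.25, b: 0.10},  # depleted (ratio 0.4 < 0.5)
        {a: 0.20, b: 0.45},
    ]
    clusters = []
    for i, p in enumerate(props):
        lo = i * markers_per_cluster
        hi = min((i + 1) * markers_per_cluster, n_genes)
        clusters.append(
            ClusterSpec(name=f"C{i + 1}", proportions=p, marker_genes=list(range(lo, hi)))
        )
    return clusters


def null_spec(seed: int = 0, **kwargs) -> SyntheticSpec:
    """A structureless design: one cluster, identical groups, no markers."""
    spec = SyntheticSpec(seed=seed, clusters=[ClusterSpec(
        name="C1", proportions={"WT": 1.0, "eKO": 1.0}, marker_genes=[]
    )], **kwargs)
    return spec


def identical_groups_spec(seed: int = 0) -> SyntheticSpec:
    """Four clusters at equal composition in both groups (no absence)."""
    clusters = default_clusters()
    for c in clusters:
        p = c.proportions["WT"]
        c.proportions = {"WT": p, "eKO": p}
    return SyntheticSpec(seed=seed, clusters=clusters)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    cell_cluster: np.ndarray  # 1-based planted cluster per cell
    cell_group: np.ndarray
    cell_plate: np.ndarray
    cell_well: np.ndarray
    gene_marker_of: np.ndarray  # 0 = background, else 1-based cluster
    extras: dict = field(default_factory=dict)


def generate_ct(spec: SyntheticSpec | None = None, seed: int | None = None):
    """Draw a Ct matrix with planted subpopulation structure.

    Each cell's Ct for gene g is Normal(mean, sd) where the mean is the
    background Ct minus ``marker_shift`` if g is one of the cell's
    cluster's markers; each reaction independently fails with the
    cluster's dropout probability.  Cells are split evenly between groups
    and filled into plates/wells in sort order.  Returns
    ``(CtMatrix, GroundTruth)``.
    """
    if spec is None:
        spec = SyntheticSpec(seed=seed if seed is not None else 0)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_cells, n_genes = spec.n_cells, spec.n_genes
    groups = list(spec.groups)
    n_per_group = n_cells // len(groups)

    cell_group = np.repeat(groups, n_per_group)
    # remainder cells (if any) go to the last group
    if len(cell_group) < n_cells:
        cell_group = np.concatenate(
            [cell_group, [groups[-1]] * (n_cells - len(cell_group))]
        )

    k = len(spec.clusters)
    cell_cluster = np.empty(n_cells, dtype=int)
    for g in groups:
        sel = np.flatnonzero(cell_group == g)
        p = np.array([c.proportions.get(g, 0.0) for c in spec.clusters])
        cell_cluster[sel] = rng.choice(k, size=len(sel), p=p) + 1

    mean_profiles = np.full((k, n_genes), spec.background_ct)
    gene_marker_of = np.zeros(n_genes, dtype=int)
    for i, c in enumerate(spec.clusters):
        mean_profiles[i, c.marker_genes] -= spec.marker_shift
        gene_marker_of[c.marker_genes] = i + 1

    sds = np.array([c.ct_sd for c in spec.clusters])
    dropouts = np.array([c.dropout for c in spec.clusters])
    idx = cell_cluster - 1
    ct = rng.normal(mean_profiles[idx], sds[idx][:, None])
    failed = rng.random((n_cells, n_genes)) < dropouts[idx][:, None]
    ct = np.where(failed, np.nan, ct)

    plates = np.arange(n_cells) // spec.wells_per_plate + 1
    wells = np.arange(n_cells) % spec.wells_per_plate + 1
    meta = pd.DataFrame(
        {
            "plate": [f"P{p}" for p in plates],
            "well": [f"W{w:02d}" for w in wells],
            "group": cell_group,
        }
    )
    m = CtMatrix(
        cells=[f"cell{i + 1:03d}" for i in range(n_cells)],
        genes=[f"G{j + 1:02d}" for j in range(n_genes)],
        ct=ct,
        failed=failed,
        meta=meta,
    )
    truth = GroundTruth(
        cell_cluster=cell_cluster,
        cell_group=np.asarray(cell_group),
        cell_plate=plates,
        cell_well=wells,
        gene_marker_of=gene_marker_of,
    )
    return m, truth


def generate_image(
    n_nuclei: int,
    nucleus_radius_px: int = 4,
    stain_boxes=(),
    noise_sd: float = 0.0,
    shape=(128, 128),
    seed: int = 0,
    max_tries: int = 10_000,
):
    """Render a ground-truthed RGB fluorescence image.

    Blue disks (nuclei) are placed without overlap by rejection sampling;
    ``stain_boxes`` are ``(channel, row, col, height, width, intensity)``
    rectangles with channel in {'red', 'green'}.  Gaussian noise of sd
    ``noise_sd`` is added per channel, then the image is clipped to
    [0, 1].  Returns ``(image, GroundTruth)`` with nucleus centers/radii
    and stain regions recorded in ``extras``.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.zeros((h, w, 3), dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    centers = []
    r = nucleus_radius_px
    tries = 0
    while len(centers) < n_nuclei:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not pack {n_nuclei} radius-{r} nuclei into {shape}"
            )
        cy, cx = rng.integers(r, h - r), rng.integers(r, w - r)
        if all((cy - py) ** 2 + (cx - px) ** 2 > (2 * r + 2) ** 2 for py, px in centers):
            centers.append((int(cy), int(cx)))
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r, 2] = 1.0

    chan = {"red": 0, "green": 1}
    for channel, row, col, bh, bw, intensity in stain_boxes:
        img[row : row + bh, col : col + bw, chan[channel]] = intensity

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    truth = GroundTruth(
        cell_cluster=np.array([]),
        cell_group=np.array([]),
        cell_plate=np.array([]),
        cell_well=np.array([]),
        gene_marker_of=np.array([]),
        extras={
            "nucleus_centers": centers,
            "nucleus_radius_px": r,
            "stain_boxes": list(stain_boxes),
        },
    )
    return img, truth


def disk_area_px(radius: int) -> int:
    """Pixel count of a rasterized disk (x^2 + y^2 <= r^2 on the grid)."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return int(np.sum(yy**2 + xx**2 <= radius * radius))


def generate_tumor_table(
    n_subjects: int,
    days=(0, 2, 4, 6, 8, 10, 12, 14),
    final_dim_cm: float = 1.0,
    growth_rate: float = 0.4,
    density_target: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Caliper measurement table under logistic growth.

    Each subject's L, W, H follow a shared logistic curve toward
    ``final_dim_cm`` with optional Gaussian measurement noise; the explant
    (last-day) mass is set so true density equals ``density_target``.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    days = np.asarray(days)
    t_mid = days[-1] / 2
    dim = final_dim_cm / (1.0 + np.exp(-growth_rate * (days - t_mid)))
    rows = []
    for s in range(1, n_subjects + 1):
        for i, d in enumerate(days):
            L, W, H = np.maximum(
                dim[i] + rng.normal(0, noise_sd, 3), 1e-6
            )
            mass = np.nan
            if d == days[-1]:
                mass = density_target * 0.5 * L * W * H
            rows.append(
                {"subject": f"S{s}", "day": int(d), "L": L, "W": W, "H": H, "mass": mass}
            )
    return pd.DataFrame(rows)
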