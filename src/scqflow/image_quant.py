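"""Immunofluorescence stain quantification.

Quantifies RGB fluorescence micrographs the way wound-section stains are
scored: the blue (DAPI, nuclear) channel is binarized with an automated
image-specific threshold (Otsu by default) and nuclei are counted as
8-connected components strictly larger than a pixel-size filter (default
15 px), which removes debris and partial nuclei; the red and green protein
stains are binarized at a fixed threshold (default 0.30 on unit-scaled
intensity) held constant across all images of the same stain so areas stay
comparable; stained area is then normalized per cell by dividing by the
nucleus count.

Images may be 8- or 16-bit or float; intensities are rescaled to [0, 1]
before thresholding.  Touching nuclei are not split (no watershed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.util import img_as_float


@dataclass
class ImageQuantResult:
    """Per-image quantification: nuclei plus stain area in each channel."""

    nuclei_count: int
    red_area_px: int
    green_area_px: int
    red_area_fraction: float
    green_area_fraction: float
    red_area_per_cell: float  # px/cell; NaN when no nuclei
    green_area_per_cell: float
    dapi_threshold: float
    dapi_method: str
    stain_threshold: float
    min_nucleus_px: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _count_nuclei(blue: np.ndarray, method: str, fixed_value: float, min_px: int):
    if method == "otsu":
        if np.ptp(blue) == 0:
            thr = float(blue.flat[0])  # flat channel: nothing to segment
        else:
            thr = float(threshold_otsu(blue))
    elif method == "fixed":
        thr = float(fixed_value)
    else:
        raise ValueError(f"unknown dapi_method {method!r}")
    mask = blue > thr
    labels = measure.label(mask, connectivity=2)  # 8-connected
    sizes = np.bincount(labels.ravel())[1:]
    count = int(np.sum(sizes > min_px))  # strictly greater
    return count, thr


def quantify_image(
    img: np.ndarray,
    stain_threshold: float = 0.3,
    min_nucleus_px: int = 15,
    dapi_method: str = "otsu",
    dapi_fixed_value: float = 0.3,
) -> ImageQuantResult:
    """Quantify one RGB micrograph.

    Parameters
    ----------
    img : ndarray of shape (H, W, 3)
        RGB image; integer dtypes are rescaled to [0, 1].
    stain_threshold : float, default 0.3
        Fixed binarization threshold for the red and green stain channels
        (pixels strictly above count as stained).
    min_nucleus_px : int, default 15
        A DAPI connected component must exceed this pixel count to be
        counted as a nucleus.
    dapi_method : {'otsu', 'fixed'}
        Automated image-specific threshold (default) or a fixed value for
        the blue channel.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an RGB (H, W, 3) image, got shape {img.shape}")
    img = img_as_float(img)
    red, green, blue = img[..., 0], img[..., 1], img[..., 2]
    total_px = red.size

    nuclei, dapi_thr = _count_nuclei(blue, dapi_method, dapi_fixed_value, min_nucleus_px)

    red_area = int(np.sum(red > stain_threshold))
    green_area = int(np.sum(green > stain_threshold))
    if nuclei == 0:
        warnings.warn("no nuclei detected; area_per_cell undefined", UserWarning)
        red_apc = green_apc = math.nan
    else:
        red_apc = red_area / nuclei
        green_apc = green_area / nuclei
    return ImageQuantResult(
        nuclei_count=nuclei,
        red_area_px=red_area,
        green_area_px=green_area,
        red_area_fraction=red_area / total_px,
        green_area_fraction=green_area / total_px,
        red_area_per_cell=red_apc,
        green_area_per_cell=green_apc,
        dapi_threshold=dapi_thr,
        dapi_method=dapi_method,
        stain_threshold=stain_threshold,
        min_nucleus_px=min_nucleus_px,
    )


def batch_quantify(
    directory,
    stain_threshold: float = 0.3,
    min_nucleus_px: int = 15,
    dapi_method: str = "otsu",
    groups: dict | None = None,
) -> pd.DataFrame:
    """Quantify every TIFF/PNG in a folder; one row per readable image.

    ``groups`` optionally maps file names to group labels; when given, the
    returned frame carries per-group mean and SEM of area-per-cell in
    ``DataFrame.attrs['group_summary']``.  Unreadable files are skipped
    with a warning.
    """
    import imageio.v3 as iio

    directory = Path(directory)
    rows = []
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() not in {".tif", ".tiff", ".png"}:
            continue
        try:
            img = iio.imread(p)
        except Exception as exc:  # unreadable file: skip, keep going
            warnings.warn(f"skipping unreadable image {p.name}: {exc}", UserWarning)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            r = quantify_image(
                img,
                stain_threshold=stain_threshold,
                min_nucleus_px=min_nucleus_px,
                dapi_method=dapi_method,
            )
        row = {"image": p.name, **r.to_dict()}
        if groups is not None:
            row["group"] = groups.get(p.name, "")
        rows.append(row)
    df = pd.DataFrame(rows)
    if groups is not None and len(df):
        summary = (
            df.groupby("group")[["red_area_per_cell", "green_area_per_cell"]]
            .agg(["mean", "sem"])
        )
        df.attrs["group_summary"] = summary
    return df
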