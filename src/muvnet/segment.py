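"""Binarization and shape-based rejection of non-vessel objects.

The segmentation stage reproduces the standard workflow for quantifying
self-assembled microvessels in fluorescence composites: a gray-level
threshold converts the single-channel image to a binary mask, connected
regions are labeled, and regions that are too small or too round --
single endothelial or stromal cells rather than elongated vessel
segments -- are rejected by thresholds on pixel count and on the
second-moment eccentricity.  Irregular debris that survives the shape
filter is removed through explicit exclusion polygons, the scriptable
replacement for interactive region drawing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label
from skimage.measure import regionprops_table

__all__ = [
    "GrayImage",
    "BinaryMask",
    "FilterParams",
    "ValidationError",
    "binarize",
    "label_components",
    "filter_components",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def _bit_depth_max(bit_depth: int) -> int:
    if bit_depth not in (8, 16):
        raise ValidationError(f"bit_depth must be 8 or 16, got {bit_depth}")
    return (1 << bit_depth) - 1


@dataclass
class GrayImage:
    """Calibrated single-channel intensity image.

    Parameters
    ----------
    pixels : 2D array
        Intensity values within the bit-depth range.
    pixel_size : float
        Lateral calibration in micrometres per pixel.
    bit_depth : int
        8 or 16; defines the intensity normalization used by thresholds.
    """

    pixels: np.ndarray
    pixel_size: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError("GrayImage requires a 2D array")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        vmax = _bit_depth_max(self.bit_depth)
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > vmax):
            raise ValidationError(
                f"intensities outside [0, {vmax}] for bit depth {self.bit_depth}"
            )

    @property
    def normalized(self) -> np.ndarray:
        """Intensities rescaled to [0, 1] by the bit-depth maximum."""
        return self.pixels.astype(float) / _bit_depth_max(self.bit_depth)


@dataclass
class BinaryMask:
    """Boolean foreground mask aligned with its source image."""

    pixels: np.ndarray
    pixel_size: float
    threshold: float | None = None  # normalized threshold actually applied
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValidationError("BinaryMask requires a 2D array")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")


@dataclass
class FilterParams:
    """Shape-filter settings for single-cell and debris rejection.

    ``min_area_px`` and ``min_eccentricity`` implement the two documented
    rejection thresholds; a region is removed when it is too small *or*
    too round under the default ``rule="or"`` (both conditions must hold
    with ``rule="and"``).  ``exclusion_polygons`` are pixel-coordinate
    vertex lists (x rightward, y downward, origin top-left) whose
    interiors are removed unconditionally.
    """

    min_area_px: int = 200
    min_eccentricity: float = 0.8
    rule: Literal["or", "and"] = "or"
    exclusion_polygons: Sequence[Sequence[Sequence[float]]] = ()

    def __post_init__(self) -> None:
        if self.min_area_px < 0:
            raise ValidationError("min_area_px must be >= 0")
        if not 0.0 <= self.min_eccentricity < 1.0:
            raise ValidationError("min_eccentricity must be in [0, 1)")
        if self.rule not in ("or", "and"):
            raise ValidationError("rule must be 'or' or 'and'")


def binarize(
    image: GrayImage,
    method: Literal["otsu", "fixed"] = "otsu",
    fixed_threshold: float | None = None,
) -> BinaryMask:
    """Threshold a grayscale image into a foreground mask.

    Foreground is strictly greater than the threshold.  With
    ``method="otsu"`` the threshold is chosen by Otsu's criterion on the
    intensity histogram; a constant image has no separable modes and
    raises :class:`ValidationError` (supply a fixed threshold instead).
    With ``method="fixed"``, ``fixed_threshold`` is given on the
    normalized [0, 1] scale and rescaled to the image bit depth.

    The normalized threshold actually applied is recorded on the
    returned mask (``mask.threshold``).
    """
    data = image.pixels
    vmax = _bit_depth_max(image.bit_depth)
    if method == "otsu":
        if data.size == 0 or data.min() == data.max():
            raise ValidationError(
                "Otsu threshold undefined on a constant image; "
                "use method='fixed' with an explicit threshold"
            )
        thr = float(threshold_otsu(data))
    elif method == "fixed":
        if fixed_threshold is None or not 0.0 <= fixed_threshold <= 1.0:
            raise ValidationError("fixed_threshold must be given in [0, 1]")
        thr = fixed_threshold * vmax
    else:
        raise ValidationError(f"unknown threshold method {method!r}")
    mask = data > thr
    return BinaryMask(
        pixels=mask,
        pixel_size=image.pixel_size,
        threshold=thr / vmax,
        metadata={"method": method},
    )


_REGION_PROPS = ("label", "area", "eccentricity", "centroid", "bbox")


def label_components(mask: BinaryMask, connectivity: Literal[4, 8] = 8) -> pd.DataFrame:
    """Label connected foreground regions and tabulate their shape.

    Returns a region table with one row per connected component and
    columns ``label``, ``area_px``, ``eccentricity``, ``centroid_x``,
    ``centroid_y`` (pixel coordinates, x rightward, y downward) and the
    bounding box.  Eccentricity is that of the ellipse with the same
    second central moments as the region, ``sqrt(1 - (minor/major)**2)``:
    0 for a circle, approaching 1 for a line.  An empty mask yields an
    empty table.
    """
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")
    conn = 1 if connectivity == 4 else 2
    labels = _sk_label(mask.pixels, connectivity=conn)
    if labels.max() == 0:
        return pd.DataFrame(
            columns=[
                "label", "area_px", "eccentricity", "centroid_x", "centroid_y",
                "bbox_min_row", "bbox_min_col", "bbox_max_row", "bbox_max_col",
            ]
        )
    props = regionprops_table(labels, properties=_REGION_PROPS)
    table = pd.DataFrame(props).rename(
        columns={
            "area": "area_px",
            "centroid-0": "centroid_y",
            "centroid-1": "centroid_x",
            "bbox-0": "bbox_min_row",
            "bbox-1": "bbox_min_col",
            "bbox-2": "bbox_max_row",
            "bbox-3": "bbox_max_col",
        }
    )
    table["area_px"] = table["area_px"].astype(int)
    return table[
        [
            "label", "area_px", "eccentricity", "centroid_x", "centroid_y",
            "bbox_min_row", "bbox_min_col", "bbox_max_row", "bbox_max_col",
        ]
    ]


def _exclusion_mask(
    shape: tuple[int, int],
    polygons: Sequence[Sequence[Sequence[float]]],
) -> np.ndarray:
    """Rasterize exclusion polygons ((x, y) vertex lists) to a mask."""
    excl = np.zeros(shape, dtype=bool)
    h, w = shape
    for poly in polygons:
        pts = np.asarray(poly, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValidationError("each exclusion polygon needs >= 3 (x, y) vertices")
        if (
            pts[:, 0].min() < 0
            or pts[:, 1].min() < 0
            or pts[:, 0].max() > w
            or pts[:, 1].max() > h
        ):
            raise ValidationError("exclusion polygon extends outside image bounds")
        # polygon2mask expects (row, col) = (y, x)
        excl |= polygon2mask(shape, pts[:, ::-1])
    return excl


def filter_components(
    mask: BinaryMask,
    regions: pd.DataFrame,
    params: FilterParams,
    connectivity: Literal[4, 8] = 8,
) -> BinaryMask:
    """Remove single-cell-like regions and excluded areas from a mask.

    A region is removed when ``area_px < min_area_px`` OR
    ``eccentricity < min_eccentricity`` (default rule; small objects and
    round objects are both characteristic of single cells rather than
    vessels).  With ``rule="and"`` a region must be both small and round
    to be removed.  Pixels inside any exclusion polygon are removed
    regardless of shape, mirroring manual debris deletion.

    ``regions`` must be the table computed from ``mask`` with the same
    connectivity; the operation is idempotent for fixed parameters.
    """
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")
    conn = 1 if connectivity == 4 else 2
    labels = _sk_label(mask.pixels, connectivity=conn)
    n_labels = int(labels.max())
    if len(regions) != n_labels:
        raise ValidationError(
            "region table does not match mask labeling "
            f"({len(regions)} rows vs {n_labels} components)"
        )
    keep = np.zeros(n_labels + 1, dtype=bool)
    if n_labels:
        small = regions["area_px"].to_numpy() < params.min_area_px
        round_ = regions["eccentricity"].to_numpy() < params.min_eccentricity
        removed = (small | round_) if params.rule == "or" else (small & round_)
        keep[regions["label"].to_numpy()] = ~removed
    out = keep[labels]
    if params.exclusion_polygons:
        out &= ~_exclusion_mask(mask.pixels.shape, params.exclusion_polygons)
    meta = dict(mask.metadata)
    meta["filter"] = {
        "min_area_px": params.min_area_px,
        "min_eccentricity": params.min_eccentricity,
        "rule": params.rule,
        "n_exclusion_polygons": len(params.exclusion_polygons),
    }
    return BinaryMask(
        pixels=out,
        pixel_size=mask.pixel_size,
        threshold=mask.threshold,
        metadata=meta,
    )
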