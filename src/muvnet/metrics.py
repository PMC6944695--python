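"""Per-device microvessel measurements: density, diameter, anastomosis.

Three headline metrics characterise a microvascular network in the
device's gel channel:

* **vessel density** — foreground-pixel fraction of the selected image
  area after binarization and shape filtering, a decimal fraction;
* **mean vessel diameter** — the skeleton of the filtered mask is taken
  as the vessel centreline, the local diameter at every skeleton pixel
  is twice the Euclidean distance to the nearest background pixel, and
  the reported value is the mean over skeleton pixels (approximately
  length-weighted) converted to μm;
* **anastomosis fraction** — the fraction of the device's 54 media
  pores whose evaluation window is sufficiently covered by vessel
  foreground, the computable analog of visually inspecting the tiled
  composite for vessels reaching each pore.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.morphology import skeletonize

from .segment import BinaryMask, ValidationError
from .synthgen import DeviceGeometry, N_PORES

__all__ = [
    "NetworkMetrics",
    "Skeleton",
    "vessel_density",
    "skeletonize_with_diameters",
    "mean_diameter",
    "anastomosis_fraction",
]


@dataclass
class NetworkMetrics:
    """The three per-device measurements plus the ROI size used."""

    density: float
    mean_diameter_um: float
    anastomosis_fraction: float
    roi_area_px: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValidationError("density must be a decimal fraction in [0, 1]")
        if self.mean_diameter_um < 0:
            raise ValidationError("mean_diameter_um must be >= 0")
        if not 0.0 <= self.anastomosis_fraction <= 1.0:
            raise ValidationError("anastomosis_fraction must be in [0, 1]")

    def to_json_dict(self) -> dict:
        return {
            "density": self.density,
            "mean_diameter_um": self.mean_diameter_um,
            "anastomosis_fraction": self.anastomosis_fraction,
            "roi_area_px": self.roi_area_px,
            "warnings": self.warnings,
        }


@dataclass
class Skeleton:
    """One-pixel-wide centreline with per-pixel local diameter.

    ``pixels`` is an (n, 2) array of (row, col) skeleton coordinates;
    ``local_diameter_um`` the matching local diameters (2 x Euclidean
    distance transform x pixel size).
    """

    pixels: np.ndarray
    local_diameter_um: np.ndarray
    pixel_size: float


def vessel_density(mask: BinaryMask, roi=None) -> float:
    """Foreground fraction of the region of interest.

    ``roi`` is either ``None`` (full frame, the whole gel-channel
    composite) or a polygon as an (x, y) pixel-coordinate vertex list;
    the density is (foreground pixels inside the ROI) / (pixels inside
    the ROI), a decimal fraction.  An empty ROI is an error.
    """
    fg = mask.pixels
    if roi is None:
        if fg.size == 0:
            raise ValidationError("empty image has no density")
        return float(fg.mean())
    pts = np.asarray(roi, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValidationError("ROI polygon needs >= 3 (x, y) vertices")
    inside = polygon2mask(fg.shape, pts[:, ::-1])  # (x, y) -> (row, col)
    n = int(inside.sum())
    if n == 0:
        raise ValidationError("ROI polygon selects no pixels")
    return float(fg[inside].sum() / n)


def _prune_spurs(skel: np.ndarray, max_spur_px: float) -> np.ndarray:
    """Remove terminal branches shorter than ``max_spur_px`` pixels.

    Only branches that run from an endpoint into a junction (degree >= 3
    pixel) are candidates; an isolated arc between two endpoints is kept
    whole, so a simple vessel is never erased by its own pruning.
    """
    skel = skel.copy()
    coords = np.argwhere(skel)
    if len(coords) == 0:
        return skel
    index = {tuple(c): True for c in coords}
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
               if (dr, dc) != (0, 0)]

    def neighbors(p):
        return [
            (p[0] + dr, p[1] + dc) for dr, dc in offsets
            if (p[0] + dr, p[1] + dc) in index
        ]

    degree = {p: len(neighbors(p)) for p in index}
    endpoints = [p for p, d in degree.items() if d == 1]
    to_remove: set[tuple[int, int]] = set()
    for ep in endpoints:
        path = [ep]
        prev, cur = None, ep
        while True:
            nbrs = [q for q in neighbors(cur) if q != prev]
            if degree[cur] >= 3 and cur != ep:
                # reached a junction: spur is the path excluding the junction
                if len(path) - 1 <= max_spur_px:
                    to_remove.update(path[:-1])
                break
            if len(nbrs) != 1 or len(path) > max_spur_px + 1:
                break  # another endpoint, a fork, or too long: keep
            prev, cur = cur, nbrs[0]
            path.append(cur)
    for p in to_remove:
        skel[p] = False
    return skel


def skeletonize_with_diameters(mask: BinaryMask, prune: bool = True) -> Skeleton:
    """Thin the mask to its centreline and attach local diameters.

    Local diameter at a skeleton pixel is twice the Euclidean distance
    to the nearest background pixel, in μm.  With ``prune=True``,
    terminal spurs shorter than the maximum local diameter (thinning
    artifacts at branch tips and tube ends) are removed before
    reporting, since they bias the mean diameter low.
    """
    fg = mask.pixels
    if not fg.any():
        return Skeleton(
            pixels=np.empty((0, 2), dtype=int),
            local_diameter_um=np.empty(0),
            pixel_size=mask.pixel_size,
        )
    skel = skeletonize(fg)
    edt = ndimage.distance_transform_edt(fg)
    if prune and skel.any():
        max_d_px = float(2.0 * edt[skel].max())
        pruned = _prune_spurs(skel, max_d_px)
        if pruned.any():
            skel = pruned
    coords = np.argwhere(skel)
    local = 2.0 * edt[skel] * mask.pixel_size
    return Skeleton(pixels=coords, local_diameter_um=local,
                    pixel_size=mask.pixel_size)


def mean_diameter(mask: BinaryMask, prune: bool = True) -> float:
    """Mean local vessel diameter over skeleton pixels, in μm.

    An empty mask (no vessels, e.g. a fully regressed network) returns
    the sentinel 0 μm and emits a warning rather than failing.
    """
    skel = skeletonize_with_diameters(mask, prune=prune)
    if len(skel.local_diameter_um) == 0:
        warnings.warn("empty vessel mask: mean diameter reported as 0 μm",
                      stacklevel=2)
        return 0.0
    return float(skel.local_diameter_um.mean())


def anastomosis_fraction(
    mask: BinaryMask,
    geometry: DeviceGeometry,
    coverage_min: float = 0.1,
) -> float:
    """Fraction of the 54 media pores reached by the vessel network.

    A pore counts as anastomosed when the vessel-foreground coverage of
    its evaluation disk (radius ``geometry.pore_window_radius``, clipped
    to the image) is at least ``coverage_min``; the default 0.1 lets a
    thin vessel touching the pore count, mirroring visual inspection.
    Returns k/54 for k anastomosed pores.
    """
    if not 0 < coverage_min <= 1:
        raise ValidationError("coverage_min must be in (0, 1]")
    px = mask.pixel_size
    ny, nx = mask.pixels.shape
    if geometry.channel_length > nx * px + px or geometry.channel_width > ny * px + px:
        raise ValidationError(
            "device geometry extends outside the image "
            f"({nx}x{ny} px at {px} μm/px vs "
            f"{geometry.channel_length}x{geometry.channel_width} μm channel)"
        )
    r = geometry.pore_window_radius
    n_anastomosed = 0
    for (x_um, y_um) in geometry.pore_positions:
        x0 = max(int((x_um - r) / px) - 1, 0)
        x1 = min(int((x_um + r) / px) + 2, nx)
        y0 = max(int((y_um - r) / px) - 1, 0)
        y1 = min(int((y_um + r) / px) + 2, ny)
        cols = (np.arange(x0, x1) + 0.5) * px
        rows = (np.arange(y0, y1) + 0.5) * px
        X, Y = np.meshgrid(cols, rows)
        window = np.hypot(X - x_um, Y - y_um) <= r
        total = int(window.sum())
        if total == 0:
            continue
        covered = int(mask.pixels[y0:y1, x0:x1][window].sum())
        if covered / total >= coverage_min:
            n_anastomosed += 1
    return n_anastomosed / N_PORES
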