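"""3D stromal-cell / vessel contact classification on two-channel z-stacks.

Confocal association studies score a stromal cell (fibroblast or
pericyte, cyan channel) as "associated" with a microvessel (endothelial,
red channel) when the two are in direct contact somewhere in the imaged
volume.  This module makes that criterion explicit and computable: after
per-channel thresholding, a cell component is associated iff any of its
voxels lies within ``contact_radius_voxels`` face-adjacency steps of a
vessel voxel, evaluated in full 3D.

Contact is measured in voxel units by default -- the computable analog
of scanning serial sections slice by slice -- with an optional metric
mode that converts a micrometre radius to per-axis voxel steps for
anisotropic stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .segment import ValidationError

__all__ = [
    "ZStack",
    "AssociationResult",
    "segment_channels",
    "associate",
]


@dataclass
class ZStack:
    """Two-channel 3D stack: vessels (red) and stromal cells (green).

    Arrays are indexed (z, y, x); ``voxel_size`` is (x, y, z) in μm.
    """

    red_channel: np.ndarray
    green_channel: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.red_channel = np.asarray(self.red_channel)
        self.green_channel = np.asarray(self.green_channel)
        if self.red_channel.ndim != 3 or self.green_channel.ndim != 3:
            raise ValidationError("z-stack channels must be 3D arrays")
        if self.red_channel.shape != self.green_channel.shape:
            raise ValidationError("red and green channels must share a shape")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size must be three positive values (x, y, z)")


@dataclass
class AssociationResult:
    """Contact-association statistic over the stromal cells of one field."""

    n_cells: int
    n_associated: int
    associated: tuple[bool, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if not 0 <= self.n_associated <= self.n_cells:
            raise ValidationError("n_associated must lie in [0, n_cells]")

    @property
    def fraction(self) -> float:
        return self.n_associated / self.n_cells


def segment_channels(
    stack: ZStack,
    red_threshold: float = 0.5,
    green_threshold: float = 0.5,
    min_cell_voxels: int = 10,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Threshold both channels and extract stromal-cell components.

    Thresholds are on the normalized [0, 1] intensity scale (each
    channel is normalized by its dtype maximum for integer stacks, or
    taken as-is for float stacks).  The vessel mask is the thresholded
    red channel; stromal cells are the 26-connected components of the
    thresholded green channel with at least ``min_cell_voxels`` voxels.

    Returns ``(vessel_mask, cell_regions)`` where ``cell_regions`` is a
    list of boolean masks, one per retained cell.  An all-zero green
    channel simply yields an empty list.
    """

    def _norm(a: np.ndarray) -> np.ndarray:
        if np.issubdtype(a.dtype, np.integer):
            return a.astype(float) / np.iinfo(a.dtype).max
        return a.astype(float)

    vessel_mask = _norm(stack.red_channel) > red_threshold
    green = _norm(stack.green_channel) > green_threshold
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n = ndimage.label(green, structure=structure)
    cells: list[np.ndarray] = []
    if n:
        counts = np.bincount(labels.ravel())
        for lab in range(1, n + 1):
            if counts[lab] >= min_cell_voxels:
                cells.append(labels == lab)
    return vessel_mask, cells


def _face_structure() -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1)


def associate(
    vessel_mask: np.ndarray,
    cell_regions: Sequence[np.ndarray],
    contact_radius_voxels: int = 1,
) -> AssociationResult:
    """Classify each stromal cell as in contact with the vessel mask.

    A cell is associated iff some voxel of it is reachable from a vessel
    voxel in at most ``contact_radius_voxels`` face-adjacency steps,
    i.e. its city-block distance to the vessel is ≤ the radius (a cell
    overlapping the vessel mask, distance 0, is trivially associated).
    The default radius 1 is direct face contact.

    Raises :class:`ValidationError` when no cells are given: the
    association fraction is undefined, not zero.
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if vessel_mask.ndim != 3:
        raise ValidationError("vessel_mask must be 3D")
    if contact_radius_voxels < 0:
        raise ValidationError("contact_radius_voxels must be >= 0")
    if len(cell_regions) == 0:
        raise ValidationError(
            "association is undefined with zero stromal cells"
        )
    if vessel_mask.any() and contact_radius_voxels > 0:
        reach = ndimage.binary_dilation(
            vessel_mask,
            structure=_face_structure(),
            iterations=contact_radius_voxels,
        )
    else:
        reach = vessel_mask
    flags = []
    for cell in cell_regions:
        cell = np.asarray(cell, dtype=bool)
        if cell.shape != vessel_mask.shape:
            raise ValidationError("cell region shape does not match vessel mask")
        flags.append(bool(np.logical_and(cell, reach).any()))
    return AssociationResult(
        n_cells=len(flags),
        n_associated=int(sum(flags)),
        associated=tuple(flags),
    )
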