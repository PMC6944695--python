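"""Seeded synthetic phantoms of microvascular networks in a microfluidic device.

The generator emulates tiled fluorescence composites of the gel channel
of a two-media-channel microfluidic device: a central channel 10.5 mm
long and 1.3 mm wide flanked by 0.5 mm media channels, communicating
through 54 pores along the two long edges.  A phantom scene consists of
an elongated branched vessel graph spanning the channel (constant
diameter per segment, tubes rasterized as disks swept along segments),
small round single-cell distractors, and irregular debris polygons.
Scenes are rendered to calibrated grayscale images (Gaussian PSF blur +
additive Gaussian noise) together with exact ground truth: a per-pixel
class label map, the vessel coverage fraction, the length-weighted true
mean diameter, and the set of pore indices reached by the network.

Every stochastic draw flows through one `numpy.random.Generator` built
from a single integer seed, so identical parameters and seed reproduce
the image and truth byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask

from .assoc3d import ZStack
from .segment import GrayImage, ValidationError

__all__ = [
    "DeviceGeometry",
    "VesselGraph",
    "PhantomScene",
    "RenderParams",
    "PhantomTruth",
    "StromalCell",
    "ZStackTruth",
    "PlacementError",
    "make_default_geometry",
    "sample_network",
    "sample_scene",
    "render",
    "render_zstack",
    "write_phantom",
    "write_zstack",
    "read_zstack",
]

N_PORES = 54  # fixed by the device: 27 on each long edge

LABEL_BACKGROUND, LABEL_VESSEL, LABEL_CELL, LABEL_DEBRIS = 0, 1, 2, 3


class PlacementError(RuntimeError):
    """An object could not be placed under its clearance constraints."""


# ---------------------------------------------------------------------------
# Device geometry
# ---------------------------------------------------------------------------

@dataclass
class DeviceGeometry:
    """Central-channel geometry and media-pore layout, in micrometres.

    The channel rectangle is [0, channel_length] x [0, channel_width]
    with x along the long axis.  The 54 pores sit on the two long edges
    (y = 0 and y = channel_width); ``pore_window_radius`` is the radius
    of the evaluation disk used to decide anastomosis at each pore.
    """

    channel_length: float = 10500.0
    channel_width: float = 1300.0
    media_channel_width: float = 500.0
    pore_positions: Sequence[tuple[float, float]] = ()
    pore_window_radius: float = 75.0

    def __post_init__(self) -> None:
        if self.pore_window_radius <= 0:
            raise ValidationError("pore_window_radius must be positive")
        if self.channel_length <= 0 or self.channel_width <= 0:
            raise ValidationError("channel dimensions must be positive")
        pores = [tuple(map(float, p)) for p in self.pore_positions]
        if len(pores) != N_PORES:
            raise ValidationError(f"exactly {N_PORES} pores required, got {len(pores)}")
        for x, y in pores:
            if not (0 <= x <= self.channel_length):
                raise ValidationError("pore x-coordinate outside channel")
            if y not in (0.0, self.channel_width):
                raise ValidationError("pores must lie on a long edge of the channel")
        for edge_y in (0.0, self.channel_width):
            xs = [x for x, y in pores if y == edge_y]
            if any(b <= a for a, b in zip(xs, xs[1:])):
                raise ValidationError("pore x-coordinates must strictly increase per edge")
        self.pore_positions = pores


def make_default_geometry(pore_window_radius: float = 75.0) -> DeviceGeometry:
    """Build the default device: 10.5 x 1.3 mm channel, 54 pores.

    The pores are laid out 27 per long edge, evenly spaced with end
    margins of half a spacing (spacing 10500/27 ≈ 388.9 μm), mirrored
    across the channel.  Pore numbering is 1..27 along the y = 0 edge
    (increasing x) then 28..54 along the opposite edge.
    """
    if pore_window_radius <= 0:
        raise ValidationError("pore_window_radius must be positive")
    length, width = 10500.0, 1300.0
    n_per_edge = N_PORES // 2
    spacing = length / n_per_edge
    xs = [(i + 0.5) * spacing for i in range(n_per_edge)]
    pores = [(x, 0.0) for x in xs] + [(x, width) for x in xs]
    return DeviceGeometry(
        channel_length=length,
        channel_width=width,
        pore_positions=pores,
        pore_window_radius=pore_window_radius,
    )


# ---------------------------------------------------------------------------
# Vessel graph and scene
# ---------------------------------------------------------------------------

@dataclass
class VesselGraph:
    """Piecewise-straight vessel network.

    ``nodes`` are (x, y) μm points; ``pore_anchors`` maps node index ->
    pore number (1-based) for nodes sitting on a media pore; ``segments``
    are (i, j, diameter_μm) triples between node indices.
    """

    nodes: np.ndarray
    segments: list[tuple[int, int, float]]
    pore_anchors: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 2)
        for i, j, d in self.segments:
            if i == j:
                raise ValidationError("self-loop segments are not allowed")
            if d <= 0:
                raise ValidationError("segment diameters must be positive")
            if not (0 <= i < len(self.nodes) and 0 <= j < len(self.nodes)):
                raise ValidationError("segment references unknown node")

    def validate_inside(self, geometry: DeviceGeometry) -> None:
        x, y = self.nodes[:, 0], self.nodes[:, 1]
        if len(self.nodes) and (
            x.min() < 0 or x.max() > geometry.channel_length
            or y.min() < 0 or y.max() > geometry.channel_width
        ):
            raise ValidationError("vessel node outside the channel rectangle")

    @property
    def connected_pores(self) -> set[int]:
        """Pore numbers (1-based) with at least one incident segment."""
        incident = set()
        for i, j, _ in self.segments:
            incident.add(i)
            incident.add(j)
        return {pore for node, pore in self.pore_anchors.items() if node in incident}

    def segment_endpoints(self) -> list[tuple[np.ndarray, np.ndarray, float]]:
        return [(self.nodes[i], self.nodes[j], d) for i, j, d in self.segments]

    def total_length(self) -> float:
        return float(sum(np.linalg.norm(b - a) for a, b, _ in self.segment_endpoints()))

    def length_weighted_mean_diameter(self) -> float:
        num = den = 0.0
        for a, b, d in self.segment_endpoints():
            L = float(np.linalg.norm(b - a))
            num += L * d
            den += L
        return num / den if den else 0.0


@dataclass
class PhantomScene:
    """A renderable phantom: vessel graph, round cells, debris polygons.

    ``cells`` are ((x, y), radius) μm disks; ``debris`` are lists of
    (x, y) μm polygon vertices.  Cells must be smaller than the thinnest
    vessel and every object centre must lie inside the channel.
    """

    graph: VesselGraph
    geometry: DeviceGeometry
    cells: list[tuple[tuple[float, float], float]] = field(default_factory=list)
    debris: list[list[tuple[float, float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.graph.validate_inside(self.geometry)
        min_radius = min((d / 2 for *_, d in self.graph.segments), default=math.inf)
        for (cx, cy), r in self.cells:
            if r <= 0:
                raise ValidationError("cell radius must be positive")
            if r >= min_radius:
                raise ValidationError(
                    "cell radii must be smaller than the minimum vessel radius"
                )
            self._check_inside(cx, cy, "cell")
        for poly in self.debris:
            cx = sum(p[0] for p in poly) / len(poly)
            cy = sum(p[1] for p in poly) / len(poly)
            self._check_inside(cx, cy, "debris")

    def _check_inside(self, x: float, y: float, what: str) -> None:
        g = self.geometry
        if not (0 <= x <= g.channel_length and 0 <= y <= g.channel_width):
            raise ValidationError(f"{what} centre outside the channel")


@dataclass
class RenderParams:
    """Imaging model parameters.

    ``psf_sigma`` is the Gaussian blur in μm applied after rasterization;
    ``background_level`` and ``noise_sd`` are fractions of full scale.
    Guard (documented, not silently enforced): the defaults must leave
    foreground separable from background at the default threshold, i.e.
    ``background_level + ~3*noise_sd`` well below the vessel amplitude.
    """

    pixel_size: float = 2.0
    psf_sigma: float = 2.0
    background_level: float = 0.05
    noise_sd: float = 0.02
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        if not 0 <= self.background_level < 1:
            raise ValidationError("background_level must be in [0, 1)")
        if self.noise_sd < 0 or self.psf_sigma < 0:
            raise ValidationError("noise_sd and psf_sigma must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValidationError("bit_depth must be 8 or 16")


@dataclass
class PhantomTruth:
    """Exact ground truth rendered alongside a phantom image."""

    coverage_fraction: float
    true_mean_diameter: float
    connected_pores: set[int]
    label_map: np.ndarray
    pixel_size: float
    cells_px: list[dict] = field(default_factory=list)
    debris_polygons_px: list[list[list[float]]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "coverage_fraction": self.coverage_fraction,
            "true_mean_diameter": self.true_mean_diameter,
            "connected_pores": sorted(self.connected_pores),
            "pixel_size": self.pixel_size,
            "cells_px": self.cells_px,
            "debris_polygons_px": self.debris_polygons_px,
            "warnings": self.warnings,
        }


# ---------------------------------------------------------------------------
# Network sampling
# ---------------------------------------------------------------------------

def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def sample_network(
    geometry: DeviceGeometry,
    n_connected_pores: int,
    diameter_mean: float = 40.0,
    diameter_sd: float = 8.0,
    branch_density: float = 1.0,
    seed: int = 0,
) -> VesselGraph:
    """Draw a random vessel network anchored at ``n_connected_pores`` pores.

    A jittered backbone polyline runs along the channel interior (kept
    clear of the pore windows), side branches sprout from backbone nodes
    at ``branch_density`` branches per mm of channel, and each selected
    pore is connected to its nearest backbone node by one straight
    vessel.  Exactly the selected pores end up anchored; per-segment
    diameters are Normal(``diameter_mean``, ``diameter_sd``) truncated
    to ±3 sd and to ≥ 4 μm.  The same seed reproduces the graph exactly.
    """
    if not 0 <= n_connected_pores <= len(geometry.pore_positions):
        raise ValidationError(
            f"n_connected_pores must be in [0, {len(geometry.pore_positions)}]"
        )
    if diameter_mean <= 0:
        raise ValidationError("diameter_mean must be positive")
    if diameter_sd < 0 or branch_density < 0:
        raise ValidationError("diameter_sd and branch_density must be >= 0")
    rng = np.random.default_rng(seed)
    L, W = geometry.channel_length, geometry.channel_width
    d_cap = diameter_mean + 3 * diameter_sd
    # interior band for backbone/branch nodes, clear of every pore window
    y_lo = max(0.25 * W, geometry.pore_window_radius + d_cap / 2 + 25.0)
    y_hi = W - y_lo
    if y_lo >= y_hi:
        raise ValidationError("vessels too thick for the channel interior band")

    nodes: list[np.ndarray] = []
    segments: list[tuple[int, int, float]] = []
    pore_anchors: dict[int, int] = {}

    def draw_diameter() -> float:
        if diameter_sd == 0:
            return diameter_mean
        lo = max(4.0, diameter_mean - 3 * diameter_sd)
        hi = diameter_mean + 3 * diameter_sd
        return float(np.clip(rng.normal(diameter_mean, diameter_sd), lo, hi))

    # backbone
    margin = min(300.0, L / 4)
    n_bb = max(2, int(round(L / 500.0)))
    xs = np.linspace(margin, L - margin, n_bb)
    ys = np.clip(W / 2 + rng.uniform(-0.2, 0.2, size=n_bb) * W, y_lo, y_hi)
    bb_idx = []
    for x, y in zip(xs, ys):
        bb_idx.append(len(nodes))
        nodes.append(np.array([x, y]))
    for i, j in zip(bb_idx, bb_idx[1:]):
        segments.append((i, j, draw_diameter()))

    # side branches from random backbone nodes, endpoints in the interior band
    n_branches = int(round(branch_density * L / 1000.0))
    for _ in range(n_branches):
        src = int(rng.choice(bb_idx))
        dx = rng.uniform(150.0, 450.0) * rng.choice([-1.0, 1.0])
        x = float(np.clip(nodes[src][0] + dx, margin / 2, L - margin / 2))
        y = float(rng.uniform(y_lo, y_hi))
        tip = len(nodes)
        nodes.append(np.array([x, y]))
        segments.append((src, tip, draw_diameter()))

    # pore connectors
    chosen = sorted(rng.choice(len(geometry.pore_positions), size=n_connected_pores,
                               replace=False).tolist())
    bb_xy = np.array([nodes[i] for i in bb_idx])
    for pore_i in chosen:
        px, py = geometry.pore_positions[pore_i]
        p = np.array([px, py])
        nearest = bb_idx[int(np.argmin(np.linalg.norm(bb_xy - p, axis=1)))]
        pn = len(nodes)
        nodes.append(p)
        pore_anchors[pn] = pore_i + 1
        segments.append((pn, nearest, draw_diameter()))

    graph = VesselGraph(nodes=np.array(nodes), segments=segments,
                        pore_anchors=pore_anchors)
    graph.validate_inside(geometry)
    return graph


def _min_distance_to_graph(p: np.ndarray, graph: VesselGraph) -> float:
    """Distance from a point to the nearest vessel *surface* (axis - radius)."""
    best = math.inf
    for a, b, d in graph.segment_endpoints():
        best = min(best, _point_segment_distance(p, a, b) - d / 2)
    return best


def sample_scene(
    geometry: DeviceGeometry,
    n_connected_pores: int = 20,
    n_cells: int = 40,
    n_debris: int = 3,
    diameter_mean: float = 40.0,
    diameter_sd: float = 8.0,
    branch_density: float = 1.0,
    cell_radius_range: tuple[float, float] = (6.0, 15.0),
    seed: int = 0,
    max_attempts: int = 2000,
) -> PhantomScene:
    """Compose a full phantom scene: network, single cells, debris.

    Cells (round, radius ≤ 15 μm by default) and debris polygons are
    placed by rejection sampling with clearances: 15 μm from any vessel
    surface, 10 μm outside every pore window, and 15 μm between objects,
    so rendered classes stay pixel-disjoint and pore-window coverage is
    owed to vessels alone.  The cell-radius range is clipped below the
    thinnest vessel radius of the sampled network (single cells are
    smaller than vessels by definition).  Raises
    :class:`PlacementError` if a clearance cannot be met within
    ``max_attempts`` draws.
    """
    rng = np.random.default_rng(seed)
    graph = sample_network(
        geometry, n_connected_pores, diameter_mean, diameter_sd,
        branch_density, seed=int(rng.integers(2**31 - 1)),
    )
    L, W = geometry.channel_length, geometry.channel_width
    pores = np.array(geometry.pore_positions)
    clearance = 15.0
    min_vessel_radius = min((d / 2 for *_, d in graph.segments), default=math.inf)
    r_hi = min(cell_radius_range[1], 0.95 * min_vessel_radius)
    r_lo = min(cell_radius_range[0], 0.6 * r_hi)
    if n_cells and r_hi <= 0:
        raise ValidationError("vessels too thin to host strictly smaller cells")

    placed: list[tuple[np.ndarray, float]] = []  # (centre, outer radius)

    def ok(p: np.ndarray, r: float) -> bool:
        if _min_distance_to_graph(p, graph) < r + clearance:
            return False
        if len(pores) and (
            np.linalg.norm(pores - p, axis=1).min()
            < geometry.pore_window_radius + r + 10.0
        ):
            return False
        return all(
            np.linalg.norm(p - q) >= r + rq + clearance for q, rq in placed
        )

    def place(r: float, what: str) -> np.ndarray:
        for _ in range(max_attempts):
            p = np.array([rng.uniform(r, L - r), rng.uniform(r, W - r)])
            if ok(p, r):
                placed.append((p, r))
                return p
        raise PlacementError(f"could not place {what} of radius {r:.1f} μm")

    cells = []
    for _ in range(n_cells):
        r = float(rng.uniform(r_lo, r_hi))
        p = place(r, "cell")
        cells.append(((float(p[0]), float(p[1])), r))

    debris = []
    for _ in range(n_debris):
        r_out = float(rng.uniform(25.0, 60.0))
        p = place(r_out, "debris")
        k = 8
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=k))
        radii = rng.uniform(0.4 * r_out, r_out, size=k)
        poly = [
            (float(p[0] + rr * np.cos(a)), float(p[1] + rr * np.sin(a)))
            for a, rr in zip(angles, radii)
        ]
        debris.append(poly)

    return PhantomScene(graph=graph, geometry=geometry, cells=cells, debris=debris)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

AMPLITUDE = {LABEL_VESSEL: 1.0, LABEL_CELL: 0.85, LABEL_DEBRIS: 0.6}


def _segment_mask_into(
    label_map: np.ndarray, a: np.ndarray, b: np.ndarray, d: float, px: float,
    value: int,
) -> None:
    """Paint a disk-swept tube (radius d/2 about segment ab) into the label map."""
    r = d / 2
    ny, nx = label_map.shape
    x0 = max(int((min(a[0], b[0]) - r) / px) - 1, 0)
    x1 = min(int((max(a[0], b[0]) + r) / px) + 2, nx)
    y0 = max(int((min(a[1], b[1]) - r) / px) - 1, 0)
    y1 = min(int((max(a[1], b[1]) + r) / px) + 2, ny)
    if x0 >= x1 or y0 >= y1:
        return
    cols = (np.arange(x0, x1) + 0.5) * px
    rows = (np.arange(y0, y1) + 0.5) * px
    X, Y = np.meshgrid(cols, rows)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        dist = np.hypot(X - a[0], Y - a[1])
    else:
        t = np.clip(((X - a[0]) * ab[0] + (Y - a[1]) * ab[1]) / denom, 0.0, 1.0)
        dist = np.hypot(X - (a[0] + t * ab[0]), Y - (a[1] + t * ab[1]))
    sub = label_map[y0:y1, x0:x1]
    sub[dist <= r] = value


def _rasterize_labels(scene: PhantomScene, px: float) -> np.ndarray:
    g = scene.geometry
    ny = math.ceil(g.channel_width / px)
    nx = math.ceil(g.channel_length / px)
    labels = np.zeros((ny, nx), dtype=np.uint8)
    # paint in increasing priority: debris, cells, vessels
    for poly in scene.debris:
        pts = np.asarray(poly, dtype=float) / px  # (x, y) in px
        labels[polygon2mask((ny, nx), pts[:, ::-1])] = LABEL_DEBRIS
    for (cx, cy), r in scene.cells:
        x0 = max(int((cx - r) / px) - 1, 0)
        x1 = min(int((cx + r) / px) + 2, nx)
        y0 = max(int((cy - r) / px) - 1, 0)
        y1 = min(int((cy + r) / px) + 2, ny)
        cols = (np.arange(x0, x1) + 0.5) * px
        rows = (np.arange(y0, y1) + 0.5) * px
        X, Y = np.meshgrid(cols, rows)
        sub = labels[y0:y1, x0:x1]
        sub[np.hypot(X - cx, Y - cy) <= r] = LABEL_CELL
    for a, b, d in scene.graph.segment_endpoints():
        _segment_mask_into(labels, a, b, d, px, LABEL_VESSEL)
    return labels


def render(scene: PhantomScene, params: RenderParams) -> tuple[GrayImage, PhantomTruth]:
    """Rasterize and image a phantom scene; return image plus exact truth.

    The image covers the channel rectangle at ``params.pixel_size``
    (dimensions rounded up).  Vessels are the union of disks swept along
    segments; the truth label map is pixel-aligned with the image and
    ``coverage_fraction`` is, by construction, exactly the vessel-pixel
    fraction of the label map.  A warning is recorded in the truth when
    any vessel is rendered thinner than 2 px (diameter recovery is
    unreliable below about 4 px).
    """
    px = params.pixel_size
    labels = _rasterize_labels(scene, px)
    warn: list[str] = []
    diameters = [d for *_, d in scene.graph.segments]
    if diameters and min(diameters) / px < 2:
        warn.append(
            f"thinnest vessel is {min(diameters) / px:.2f} px wide at "
            f"{px} μm/px; diameter recovery is unreliable below ~4 px"
        )
    img = np.full(labels.shape, params.background_level, dtype=float)
    for cls, amp in AMPLITUDE.items():
        img[labels == cls] = amp
    if params.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=params.psf_sigma / px)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    vmax = (1 << params.bit_depth) - 1
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    quantized = np.clip(np.rint(img * vmax), 0, vmax).astype(dtype)

    truth = PhantomTruth(
        coverage_fraction=float((labels == LABEL_VESSEL).mean()),
        true_mean_diameter=scene.graph.length_weighted_mean_diameter(),
        connected_pores=scene.graph.connected_pores,
        label_map=labels,
        pixel_size=px,
        cells_px=[
            {"center_px": [cx / px, cy / px], "radius_px": r / px}
            for (cx, cy), r in scene.cells
        ],
        debris_polygons_px=[
            [[x / px, y / px] for x, y in poly] for poly in scene.debris
        ],
        warnings=warn,
    )
    return GrayImage(pixels=quantized, pixel_size=px, bit_depth=params.bit_depth), truth


# ---------------------------------------------------------------------------
# Two-channel 3D z-stacks for association studies
# ---------------------------------------------------------------------------

@dataclass
class StromalCell:
    """A stromal cell to plant in a z-stack: radius and planted contact flag."""

    radius_um: float = 8.0
    contact: bool = False

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValidationError("stromal cell radius must be positive")


@dataclass
class ZStackTruth:
    """Ground truth for a rendered two-channel z-stack."""

    n_cells: int
    contact_flags: list[bool]
    contact_fraction: float | None
    cell_centers_vox: list[tuple[int, int, int]]
    cell_radii_um: list[float]
    vessel_voxels: int
    voxel_size: tuple[float, float, float]

    def to_json_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "contact_flags": self.contact_flags,
            "contact_fraction": self.contact_fraction,
            "cell_centers_vox": [list(c) for c in self.cell_centers_vox],
            "cell_radii_um": self.cell_radii_um,
            "vessel_voxels": self.vessel_voxels,
            "voxel_size": list(self.voxel_size),
        }


def _sphere_mask(shape, center, radius_um, spacing) -> np.ndarray:
    """Voxels whose centres lie within radius_um of center (index coords)."""
    nz, ny, nx = shape
    cz, cy, cx = center
    sx, sy, sz = spacing
    rz, ry, rx = radius_um / sz, radius_um / sy, radius_um / sx
    z0, z1 = max(int(cz - rz) - 1, 0), min(int(cz + rz) + 2, nz)
    y0, y1 = max(int(cy - ry) - 1, 0), min(int(cy + ry) + 2, ny)
    x0, x1 = max(int(cx - rx) - 1, 0), min(int(cx + rx) + 2, nx)
    out = np.zeros(shape, dtype=bool)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return out
    Z, Y, X = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    d2 = ((Z - cz) * sz) ** 2 + ((Y - cy) * sy) ** 2 + ((X - cx) * sx) ** 2
    out[z0:z1, y0:y1, x0:x1] = d2 <= radius_um**2
    return out


def render_zstack(
    vessel_scene: PhantomScene,
    stromal_cells: Sequence[StromalCell],
    params: RenderParams,
    fov_um: tuple[float, float, float, float] | None = None,
    depth_um: float = 64.0,
    z_step_um: float | None = None,
    max_attempts: int = 500,
) -> tuple[ZStack, ZStackTruth]:
    """Render a confocal-like two-channel 3D field with planted contacts.

    The field of view (``fov_um`` = (x0, y0, x1, y1), default a 256 μm
    square centred on the scene's longest vessel segment) is voxelised
    at ``params.pixel_size`` laterally and ``z_step_um`` axially
    (default isotropic).  Vessel segments crossing the field become 3D
    tubes in the red channel at mid-depth (small per-segment z jitter);
    each requested stromal cell becomes a sphere in the green channel,
    placed so that a planted-contact cell shares at least one
    face-adjacent voxel pair with the vessel mask while a non-contact
    cell stays ≥ 2 voxels (Euclidean, index units) from every vessel
    voxel.  Placement that cannot satisfy these constraints within
    ``max_attempts`` draws raises :class:`PlacementError`.
    """
    px = params.pixel_size
    zs = z_step_um if z_step_um is not None else px
    if zs <= 0:
        raise ValidationError("z_step_um must be positive")
    rng = np.random.default_rng(params.seed)
    segs = vessel_scene.graph.segment_endpoints()
    if fov_um is None:
        if not segs:
            raise ValidationError("cannot centre field of view: scene has no vessels")
        a, b, _ = max(segs, key=lambda s: np.linalg.norm(s[1] - s[0]))
        c = (a + b) / 2
        half = 128.0
        fov_um = (c[0] - half, c[1] - half, c[0] + half, c[1] + half)
    x0u, y0u, x1u, y1u = fov_um
    nx = math.ceil((x1u - x0u) / px)
    ny = math.ceil((y1u - y0u) / px)
    nz = math.ceil(depth_um / zs)
    shape = (nz, ny, nx)
    spacing = (px, px, zs)

    # vessel tubes in 3D: distance from voxel centre to the segment's 3D axis
    vessel = np.zeros(shape, dtype=bool)
    Zc = (np.arange(nz) + 0.5) * zs
    Yc = (np.arange(ny) + 0.5) * px + y0u
    Xc = (np.arange(nx) + 0.5) * px + x0u
    Z, Y, X = np.meshgrid(Zc, Yc, Xc, indexing="ij")
    zmid = depth_um / 2
    for a, b, d in segs:
        r = d / 2
        if (
            max(a[0], b[0]) < x0u - r or min(a[0], b[0]) > x1u + r
            or max(a[1], b[1]) < y0u - r or min(a[1], b[1]) > y1u + r
        ):
            continue
        zc = float(np.clip(zmid + rng.uniform(-0.1, 0.1) * depth_um, r, depth_um - r))
        a3 = np.array([a[0], a[1], zc])
        b3 = np.array([b[0], b[1], zc])
        ab = b3 - a3
        denom = float(ab @ ab)
        t = np.clip(
            ((X - a3[0]) * ab[0] + (Y - a3[1]) * ab[1] + (Z - a3[2]) * ab[2])
            / (denom if denom else 1.0),
            0.0, 1.0,
        )
        d2 = (
            (X - (a3[0] + t * ab[0])) ** 2
            + (Y - (a3[1] + t * ab[1])) ** 2
            + (Z - (a3[2] + t * ab[2])) ** 2
        )
        vessel |= d2 <= r**2

    if stromal_cells and not vessel.any():
        if any(c.contact for c in stromal_cells):
            raise PlacementError("no vessel voxels in the field; cannot plant contact")

    # distance fields used to verify the planted-contact contract exactly
    if vessel.any():
        dt_taxi = ndimage.distance_transform_cdt(~vessel, metric="taxicab")
        dt_eucl, nearest_vessel = ndimage.distance_transform_edt(
            ~vessel, return_indices=True
        )
    else:
        dt_taxi = np.full(shape, np.iinfo(np.int32).max, dtype=np.int32)
        dt_eucl = np.full(shape, np.inf)
        nearest_vessel = None

    cell_mask = np.zeros(shape, dtype=bool)
    occupied_halo = np.zeros(shape, dtype=bool)  # cells + 1-voxel 26-halo
    centers: list[tuple[int, int, int]] = []
    flags: list[bool] = []
    radii: list[float] = []
    surface = np.argwhere(dt_taxi == 1)  # background voxels face-adjacent to vessel
    halo_structure = np.ones((3, 3, 3), dtype=bool)

    def _in_bounds(center, r_um) -> bool:
        # keep the whole sphere inside the volume so no cell is border-clipped
        margins = (math.ceil(r_um / zs) + 1, math.ceil(r_um / px) + 1,
                   math.ceil(r_um / px) + 1)
        return all(m <= c < dim - m
                   for c, dim, m in zip(center, shape, margins))

    for cell in stromal_cells:
        r_um = cell.radius_um
        placed = False
        for _ in range(max_attempts):
            if cell.contact:
                if len(surface) == 0:
                    break
                b_vox = surface[int(rng.integers(len(surface)))]
                # step outward from the vessel, away from the nearest vessel voxel
                s_vox = nearest_vessel[:, b_vox[0], b_vox[1], b_vox[2]]
                direction = b_vox.astype(float) - s_vox
                if np.linalg.norm(direction) < 1e-9:
                    direction = rng.normal(size=3)
                direction = direction / np.linalg.norm(direction)
                step = (r_um * 0.9) / np.array([zs, px, px])
                center = tuple(np.rint(b_vox + direction * step).astype(int))
            else:
                center = (
                    int(rng.integers(nz)), int(rng.integers(ny)), int(rng.integers(nx)),
                )
            if not _in_bounds(center, r_um):
                continue
            sphere = _sphere_mask(shape, center, r_um, spacing)
            if not sphere.any() or (sphere & occupied_halo).any():
                continue
            if cell.contact and not sphere[tuple(b_vox)]:
                continue
            dmin_taxi = int(dt_taxi[sphere].min())
            if cell.contact:
                if dmin_taxi != 1:
                    continue
            else:
                if float(dt_eucl[sphere].min()) < 2.0:
                    continue
            cell_mask |= sphere
            occupied_halo |= ndimage.binary_dilation(
                sphere, structure=halo_structure, iterations=3
            )
            centers.append(tuple(int(v) for v in center))
            flags.append(cell.contact)
            radii.append(r_um)
            placed = True
            break
        if not placed:
            kind = "contact" if cell.contact else "non-contact"
            raise PlacementError(
                f"could not place {kind} cell (radius {r_um:.1f} μm) "
                "under the adjacency constraints"
            )

    def _image(mask: np.ndarray, amp: float, sub_seed: int) -> np.ndarray:
        img = np.full(shape, params.background_level, dtype=float)
        img[mask] = amp
        if params.psf_sigma > 0:
            img = ndimage.gaussian_filter(
                img, sigma=(params.psf_sigma / zs, params.psf_sigma / px,
                            params.psf_sigma / px)
            )
        if params.noise_sd > 0:
            sub = np.random.default_rng((params.seed, sub_seed))
            img = img + sub.normal(0.0, params.noise_sd, size=shape)
        vmax = (1 << params.bit_depth) - 1
        dtype = np.uint8 if params.bit_depth == 8 else np.uint16
        return np.clip(np.rint(img * vmax), 0, vmax).astype(dtype)

    stack = ZStack(
        red_channel=_image(vessel, 1.0, 1),
        green_channel=_image(cell_mask, 0.9, 2),
        voxel_size=(px, px, zs),
    )
    n = len(flags)
    truth = ZStackTruth(
        n_cells=n,
        contact_flags=flags,
        contact_fraction=(sum(flags) / n) if n else None,
        cell_centers_vox=centers,
        cell_radii_um=radii,
        vessel_voxels=int(vessel.sum()),
        voxel_size=(px, px, zs),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# File output (TIFF images + JSON truth sidecars)
# ---------------------------------------------------------------------------

def write_phantom(out_dir: str | Path, image: GrayImage, truth: PhantomTruth) -> dict:
    """Write a phantom to disk: image.tif, labels.tif, truth.json."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / "image.tif",
        "labels": out / "labels.tif",
        "truth": out / "truth.json",
    }
    tifffile.imwrite(paths["image"], image.pixels,
                     resolution=(1e4 / image.pixel_size, 1e4 / image.pixel_size))
    tifffile.imwrite(paths["labels"], truth.label_map)
    paths["truth"].write_text(json.dumps(truth.to_json_dict(), indent=2))
    return {k: str(v) for k, v in paths.items()}


def write_zstack(out_dir: str | Path, stack: ZStack, truth: ZStackTruth) -> dict:
    """Write a z-stack as channel-interleaved multi-page TIFF + truth JSON.

    Page order is (z0 red, z0 green, z1 red, z1 green, ...); the order is
    recorded in the TIFF description metadata.
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nz = stack.red_channel.shape[0]
    pages = np.empty((2 * nz,) + stack.red_channel.shape[1:],
                     dtype=stack.red_channel.dtype)
    pages[0::2] = stack.red_channel
    pages[1::2] = stack.green_channel
    desc = json.dumps({
        "page_order": "z-major, channel-interleaved: (z0 red, z0 green, z1 red, ...)",
        "channels": ["red/vessel", "green/stromal"],
        "voxel_size_um_xyz": list(stack.voxel_size),
    })
    paths = {"stack": out / "zstack.tif", "truth": out / "zstack_truth.json"}
    tifffile.imwrite(paths["stack"], pages, description=desc)
    paths["truth"].write_text(json.dumps(truth.to_json_dict(), indent=2))
    return {k: str(v) for k, v in paths.items()}


def read_zstack(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
    red_channel: int = 0,
    green_channel: int = 1,
) -> ZStack:
    """Read a channel-interleaved multi-page TIFF z-stack back into memory."""
    import tifffile

    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        desc = tf.pages[0].description
    if voxel_size is None:
        try:
            voxel_size = tuple(json.loads(desc)["voxel_size_um_xyz"])
        except (json.JSONDecodeError, KeyError, TypeError):
            raise ValidationError(
                "voxel_size not found in TIFF metadata; pass it explicitly"
            )
    return ZStack(
        red_channel=pages[red_channel::2],
        green_channel=pages[green_channel::2],
        voxel_size=voxel_size,
    )
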