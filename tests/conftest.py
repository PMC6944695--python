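from __future__ import annotations

import numpy as np
import pytest

from muvnet import (
    BinaryMask,
    GrayImage,
    PhantomScene,
    RenderParams,
    RunConfig,
    VesselGraph,
    make_default_geometry,
)

NOISELESS = dict(psf_sigma=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def geometry():
    return make_default_geometry()


def bool_mask(array, pixel_size: float = 2.0) -> BinaryMask:
    return BinaryMask(pixels=np.asarray(array, dtype=bool), pixel_size=pixel_size)


def gray16(array01, pixel_size: float = 2.0) -> GrayImage:
    """Build a 16-bit GrayImage from a [0, 1] float array."""
    pixels = np.clip(np.rint(np.asarray(array01, dtype=float) * 65535),
                     0, 65535).astype(np.uint16)
    return GrayImage(pixels=pixels, pixel_size=pixel_size, bit_depth=16)


def single_segment_scene(geometry, a, b, diameter) -> PhantomScene:
    graph = VesselGraph(
        nodes=np.array([a, b], dtype=float),
        segments=[(0, 1, float(diameter))],
    )
    return PhantomScene(graph=graph, geometry=geometry)


def noiseless_params(pixel_size: float = 2.0, seed: int = 0) -> RenderParams:
    return RenderParams(pixel_size=pixel_size, seed=seed, **NOISELESS)


def noiseless_config(pixel_size: float = 2.0, **overrides) -> RunConfig:
    """Pipeline config matched to noiseless renders: fixed threshold between
    background (0.05) and the dimmest object class (0.6), filter area cutoff
    rescaled from the 200 px @ 2 μm/px default to the given pixel size."""
    defaults = dict(
        pixel_size=pixel_size,
        threshold_method="fixed",
        fixed_threshold=0.3,
        min_area_px=int(round(200 * (2.0 / pixel_size) ** 2)),
    )
    defaults.update(overrides)
    return RunConfig(**defaults)
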