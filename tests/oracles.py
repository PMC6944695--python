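"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is deliberately naive (pure-Python scans, BFS flood
fill, all-pairs distance checks, closed-form geometry) and shares no
code path with the package implementation it validates.
"""

from __future__ import annotations

import math
from collections import deque


def pixel_scan_count(pixels, threshold) -> int:
    """Count pixels strictly above threshold by a plain Python scan."""
    n = 0
    for row in pixels:
        for v in row:
            if v > threshold:
                n += 1
    return n


def flood_fill_components(mask, connectivity: int) -> list[set]:
    """Label foreground by BFS flood fill; returns one pixel-set per region."""
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0)]
    else:
        raise ValueError("connectivity must be 4 or 8")
    h = len(mask)
    w = len(mask[0]) if h else 0
    seen = [[False] * w for _ in range(h)]
    regions = []
    for r in range(h):
        for c in range(w):
            if mask[r][c] and not seen[r][c]:
                region = set()
                queue = deque([(r, c)])
                seen[r][c] = True
                while queue:
                    y, x = queue.popleft()
                    region.add((y, x))
                    for dy, dx in offsets:
                        ny, nx = y + dy, x + dx
                        if (0 <= ny < h and 0 <= nx < w
                                and mask[ny][nx] and not seen[ny][nx]):
                            seen[ny][nx] = True
                            queue.append((ny, nx))
                regions.append(region)
    return regions


def stadium_area(length: float, diameter: float) -> float:
    """Area of a disk swept along a straight segment (stadium shape)."""
    return length * diameter + math.pi * (diameter / 2.0) ** 2


def associate_all_pairs(vessel_mask, cell_regions, radius: int) -> list[bool]:
    """All-pairs city-block distance association: the naive 3D oracle."""
    import numpy as np

    vessel_voxels = np.argwhere(np.asarray(vessel_mask, dtype=bool))
    flags = []
    for cell in cell_regions:
        cell_voxels = np.argwhere(np.asarray(cell, dtype=bool))
        hit = False
        for cv in cell_voxels:
            for vv in vessel_voxels:
                if abs(int(cv[0]) - int(vv[0])) + abs(int(cv[1]) - int(vv[1])) \
                        + abs(int(cv[2]) - int(vv[2])) <= radius:
                    hit = True
                    break
            if hit:
                break
        flags.append(hit)
    return flags
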