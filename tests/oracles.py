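"""Brute-force reference implementations used only to cross-check the
package's Sholl machinery.  Deliberately simple and slow: ring pixels come
from rounding sqrt per octant (not the incremental midpoint recurrence),
runs are counted by an explicit walk along the ring, and 3D shell clusters
are labelled by hand-written flood fill instead of scipy labelling."""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def sqrt_ring(radius_px: int) -> set[tuple[int, int]]:
    """Pixels of the discretized circle, by per-octant sqrt rounding."""
    pts: set[tuple[int, int]] = set()
    x = 0
    while True:
        y = round(math.sqrt(radius_px * radius_px - x * x))
        if y < x:
            break
        for px, py in ((x, y), (y, x), (-x, y), (-y, x),
                       (x, -y), (y, -x), (-x, -y), (-y, -x)):
            pts.add((px, py))
        x += 1
    return pts


def walk_ring(radius_px: int) -> list[tuple[int, int]]:
    """Ring pixels in traversal order, found by walking 8-neighbours."""
    ring = sqrt_ring(radius_px)
    if radius_px == 0:
        return [(0, 0)]
    start = (radius_px, 0)
    order = [start]
    visited = {start}
    cur = start
    while True:
        nxt = None
        cx, cy = cur
        # axis-aligned neighbours first so corner pixels are not skipped
        for dx, dy in ((0, 1), (1, 0), (-1, 0), (0, -1),
                       (1, 1), (-1, 1), (1, -1), (-1, -1)):
            cand = (cx + dx, cy + dy)
            if cand in ring and cand not in visited:
                nxt = cand
                break
        if nxt is None:
            break
        order.append(nxt)
        visited.add(nxt)
        cur = nxt
    assert len(order) == len(ring), "ring walk failed to cover the circle"
    return order


def sholl_2d_crossings(pixels: np.ndarray, center_px: tuple[int, int],
                       radius_px: int) -> int:
    """Foreground runs along the circle, counted by explicit traversal."""
    ny, nx = pixels.shape
    cx, cy = center_px
    flags = []
    for dx, dy in walk_ring(radius_px):
        x, y = cx + dx, cy + dy
        flags.append(bool(pixels[y, x]) if 0 <= x < nx and 0 <= y < ny else False)
    if not any(flags):
        return 0
    if all(flags):
        return 1
    runs = 0
    prev = flags[-1]  # cyclic: seam between last and first merged
    for f in flags:
        if f and not prev:
            runs += 1
        prev = f
    return runs


def sholl_3d_components(mask: np.ndarray,
                        center_um: tuple[float, float, float],
                        voxel_size_um: tuple[float, float, float],
                        radius_um: float, dr_um: float) -> int:
    """26-connected clusters of foreground voxels in one spherical shell,
    labelled by breadth-first flood fill."""
    dx, dy, dz = voxel_size_um
    nz, ny, nx = mask.shape
    lo = radius_um - dr_um / 2
    hi = radius_um + dr_um / 2
    shell = set()
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                d = math.sqrt(((x + 0.5) * dx - center_um[0]) ** 2
                              + ((y + 0.5) * dy - center_um[1]) ** 2
                              + ((z + 0.5) * dz - center_um[2]) ** 2)
                if lo <= d < hi:
                    shell.add((z, y, x))
    comps = 0
    while shell:
        comps += 1
        seed = next(iter(shell))
        queue = deque([seed])
        shell.discard(seed)
        while queue:
            z, y, x = queue.popleft()
            for ddz in (-1, 0, 1):
                for ddy in (-1, 0, 1):
                    for ddx in (-1, 0, 1):
                        nb = (z + ddz, y + ddy, x + ddx)
                        if nb in shell:
                            shell.discard(nb)
                            queue.append(nb)
    return comps
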