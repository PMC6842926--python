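"""Brute-force reference implementations used to cross-check the package.

Everything here is deliberately naive — BFS flood fill over explicit
neighbour lists, all-pairs voxel scans — and shares no code with the package
internals (which are vectorised scipy/numpy paths).
"""

from __future__ import annotations

from collections import deque

import numpy as np


def neighbours(shape, x, y, z, connectivity):
    """Yield in-bounds neighbours of (x, y, z) under 6- or 26-connectivity."""
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                if connectivity == 6 and abs(dx) + abs(dy) + abs(dz) != 1:
                    continue
                nx, ny, nz = x + dx, y + dy, z + dz
                if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                    yield nx, ny, nz


def flood_fill_components(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    """BFS connected-component labelling of a boolean grid.

    Returns (labels, n) with labels in 1..n over True voxels, 0 elsewhere.
    """
    labels = np.zeros(mask.shape, dtype=int)
    n = 0
    for start in map(tuple, np.argwhere(mask)):
        if labels[start]:
            continue
        n += 1
        queue = deque([start])
        labels[start] = n
        while queue:
            x, y, z = queue.popleft()
            for nb in neighbours(mask.shape, x, y, z, connectivity):
                if mask[nb] and not labels[nb]:
                    labels[nb] = n
                    queue.append(nb)
    return labels, n


def enclosed_background(fg: np.ndarray) -> np.ndarray:
    """Background voxels not 6-connected to the image border (holes/gaps).

    An axis of extent 1 is degenerate (a planar image): its faces do not count
    as image border, matching the package's treatment of 2-D inputs.
    """
    bg = ~fg
    reach = np.zeros(fg.shape, dtype=bool)
    queue = deque()
    for pos in map(tuple, np.argwhere(bg)):
        if any(
            (p == 0 or p == s - 1) and s > 1 for p, s in zip(pos, fg.shape)
        ):
            if not reach[pos]:
                reach[pos] = True
                queue.append(pos)
    while queue:
        x, y, z = queue.popleft()
        for nb in neighbours(fg.shape, x, y, z, 6):
            if bg[nb] and not reach[nb]:
                reach[nb] = True
                queue.append(nb)
    return bg & ~reach


def adjacency_pairs(index_grid: np.ndarray) -> dict[tuple[int, int], int]:
    """All-pairs face-adjacency scan: for every voxel pair sharing a face with
    different indices, count one shared face for that (sorted) pair."""
    counts: dict[tuple[int, int], int] = {}
    sx, sy, sz = index_grid.shape
    for x in range(sx):
        for y in range(sy):
            for z in range(sz):
                a = index_grid[x, y, z]
                for nx, ny, nz in ((x + 1, y, z), (x, y + 1, z), (x, y, z + 1)):
                    if nx >= sx or ny >= sy or nz >= sz:
                        continue
                    b = index_grid[nx, ny, nz]
                    if a != b:
                        key = (min(a, b), max(a, b))
                        counts[key] = counts.get(key, 0) + 1
    return counts


def interior_point_oracle(grid: np.ndarray, component: np.ndarray, value) -> tuple[int, int, int]:
    """Exhaustive interior-point search: the component voxel maximising the
    city-block distance to the nearest differently-valued voxel, ties broken
    lexicographically on (x, y, z)."""
    different = np.argwhere(grid != value)
    best_pt, best_d = None, -1
    for pt in map(tuple, np.argwhere(component)):
        if len(different):
            d = int(np.abs(different - pt).sum(axis=1).min())
        else:  # uniform grid: distance to outside
            d = 1 + min(
                min(p, s - 1 - p) for p, s in zip(pt, grid.shape)
            )
        if d > best_d:
            best_pt, best_d = pt, d
    return best_pt
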