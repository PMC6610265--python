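"""Independent oracles used by the tests.

These deliberately avoid the library's own code paths: the flood fill is a
pure-Python BFS, and curve averages are dense trapezoid sums, so that the
implementation (scipy labelling, adaptive quadrature) is checked against an
independent route.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_component_3d(
    above: np.ndarray, seed: tuple[int, int, int], connectivity: int = 26
) -> set[tuple[int, int, int]]:
    """Seed-containing connected component of a boolean volume, by BFS."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    shape = above.shape
    seen = {seed}
    queue = deque([seed])
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            n = (z + dz, y + dy, x + dx)
            if (
                0 <= n[0] < shape[0]
                and 0 <= n[1] < shape[1]
                and 0 <= n[2] < shape[2]
                and n not in seen
                and above[n]
            ):
                seen.add(n)
                queue.append(n)
    return seen


def bfs_component_2d(
    above2d: np.ndarray, seed_yx: tuple[int, int], connectivity: int = 8
) -> set[tuple[int, int]]:
    """Seed-containing connected component of a boolean slice, by BFS."""
    offsets = [
        (dy, dx)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dy, dx) != (0, 0) and (connectivity == 8 or abs(dy) + abs(dx) == 1)
    ]
    shape = above2d.shape
    seen = {seed_yx}
    queue = deque([seed_yx])
    while queue:
        y, x = queue.popleft()
        for dy, dx in offsets:
            n = (y + dy, x + dx)
            if (
                0 <= n[0] < shape[0]
                and 0 <= n[1] < shape[1]
                and n not in seen
                and above2d[n]
            ):
                seen.add(n)
                queue.append(n)
    return seen


def trapezoid_frame_average(model, start: float, end: float, n: int = 10_000) -> float:
    """Dense-trapezoid mean of a kinetic curve over one frame."""
    t = np.linspace(start, end, n)
    return float(np.trapezoid(model.value(t), t) / (end - start))
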