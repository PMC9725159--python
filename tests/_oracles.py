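"""Independent brute-force oracles for the landscape metrics.

Everything here is deliberately naive — explicit loops, flood fill,
direct formula evaluation — and shares no code with the package, so a
match is evidence the vectorised implementations are right.
"""

from __future__ import annotations

import math

import numpy as np

ORTHO = ((-1, 0), (1, 0), (0, -1), (0, 1))
TEMPLATE = {
    (-1, -1): 1, (-1, 0): 2, (-1, 1): 1,
    (0, -1): 2, (0, 0): 1, (0, 1): 2,
    (1, -1): 1, (1, 0): 2, (1, 1): 1,
}  # sum = 13


def bf_label(grid: np.ndarray, nodata: int):
    """Flood-fill 4-connected labeling; returns (labels, classes, areas)."""
    nrows, ncols = grid.shape
    labels = np.zeros((nrows, ncols), dtype=int)
    classes, areas = [], []
    next_id = 0
    for r0 in range(nrows):
        for c0 in range(ncols):
            if grid[r0, c0] == nodata or labels[r0, c0]:
                continue
            next_id += 1
            code = grid[r0, c0]
            stack, area = [(r0, c0)], 0
            labels[r0, c0] = next_id
            while stack:
                r, c = stack.pop()
                area += 1
                for dr, dc in ORTHO:
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < nrows
                        and 0 <= cc < ncols
                        and not labels[rr, cc]
                        and grid[rr, cc] == code
                    ):
                        labels[rr, cc] = next_id
                        stack.append((rr, cc))
            classes.append(int(code))
            areas.append(area)
    return labels, classes, areas


def bf_adjacency(grid: np.ndarray, nodata: int) -> dict:
    """Double-count adjacency dict {(code_a, code_b): count}, orthogonal
    neighbours only, nodata pairs excluded."""
    nrows, ncols = grid.shape
    g: dict = {}
    for r in range(nrows):
        for c in range(ncols):
            a = int(grid[r, c])
            if a == nodata:
                continue
            for dr, dc in ORTHO:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols:
                    b = int(grid[rr, cc])
                    if b == nodata:
                        continue
                    g[(a, b)] = g.get((a, b), 0) + 1
    return g


def bf_pladj(grid: np.ndarray, nodata: int, code: int | None = None) -> float:
    g = bf_adjacency(grid, nodata)
    if code is None:
        like = sum(v for (a, b), v in g.items() if a == b)
        total = sum(g.values())
    else:
        like = g.get((code, code), 0)
        total = sum(v for (a, b), v in g.items() if a == code)
    return 100.0 * like / total if total > 0 else float("nan")


def bf_contig(labels: np.ndarray, patch_id: int) -> float:
    """Per-pixel 3×3 template sums over same-patch cells, averaged."""
    cells = list(zip(*np.nonzero(labels == patch_id)))
    nrows, ncols = labels.shape
    total = 0.0
    for r, c in cells:
        for (dr, dc), w in TEMPLATE.items():
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and labels[rr, cc] == patch_id:
                total += w
    return (total / len(cells) - 1.0) / 12.0


def bf_shei(grid: np.ndarray, nodata: int, subset=None) -> float:
    values = [
        int(v)
        for v in grid.ravel()
        if v != nodata and (subset is None or v in subset)
    ]
    if not values:
        return float("nan")
    counts = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    m = len(counts)
    if m <= 1:
        return 0.0
    n = len(values)
    h = -sum((k / n) * math.log(k / n) for k in counts.values())
    return h / math.log(m)


def bf_pd(n_patches: int, area_m2: float) -> float:
    return n_patches / area_m2 * 10_000.0
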