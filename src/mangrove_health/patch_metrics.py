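"""Whole-extent landscape metrics on categorical grids.

Implements the four metrics driving the health factors:

* **CONTIG** — per-patch contiguity from a 3×3 weight template
  (centre 1, orthogonal 2, diagonal 1; template sum v = 13):
  ``CONTIG = (mean_r c_r − 1) / (v − 1)``, where ``c_r`` sums template
  weights over neighbourhood cells belonging to the *same patch*.
  0 for a single-pixel patch, → 1 for large compact patches.
* **PLADJ** — percentage of like adjacencies, double-count method,
  orthogonal neighbours only: ``100 · g_ii / Σ_k g_ik`` at class scope,
  ``100 · Σ_i g_ii / Σ_ik g_ik`` at landscape scope.
* **PD** — patch density, ``n / A × 10,000`` patches per hectare with A the
  landscape area in m² (a scale factor is exposed because FRAGSTATS prints
  per 100 ha; default follows the per-hectare form).
* **SHEI** — Shannon's evenness, ``−Σ P_i ln P_i / ln m`` over the classes
  present (0 by convention when m = 1).

Patches are 4-connected: orthogonal neighbours join, diagonals do not.
Nodata cells are excluded from patches, adjacencies, proportions and area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster_io import CategoricalRaster, RasterValidationError

__all__ = [
    "PatchSet",
    "AdjacencyTable",
    "MetricValue",
    "label_patches",
    "adjacency_counts",
    "contig",
    "contig_values",
    "pladj",
    "patch_density",
    "shei",
    "shei_value",
    "label_grid",
    "adjacency_matrix",
]

#: 4-connectivity structuring element for patch labeling
FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: CONTIG 3×3 template: centre 1, orthogonal 2, diagonal 1 (sum = 13)
CONTIG_TEMPLATE = np.array([[1, 2, 1], [2, 1, 2], [1, 2, 1]], dtype=float)
CONTIG_V = float(CONTIG_TEMPLATE.sum())  # 13

LANDSCAPE = "landscape"


@dataclass(frozen=True)
class MetricValue:
    """A named metric value with its scope and units."""

    name: str
    scope: str  # "landscape", "class:<code>" or "patch:<id>"
    value: float
    units: str = ""


@dataclass
class PatchSet:
    """Connected-component labeling of a categorical grid.

    ``patch_id_grid`` holds ids 1..n (0 = background/nodata); ``patches``
    lists ``(id, class_code, area_cells)`` in id order.
    """

    patch_id_grid: np.ndarray
    patches: list[tuple[int, int, int]]
    pixel_size_m: float = 1.0

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    def area_of(self, patch_id: int) -> int:
        return self.patches[self._index(patch_id)][2]

    def class_of(self, patch_id: int) -> int:
        return self.patches[self._index(patch_id)][1]

    def _index(self, patch_id: int) -> int:
        if not 1 <= patch_id <= len(self.patches):
            raise KeyError(f"unknown patch id {patch_id}")
        return patch_id - 1

    def ids_of_class(self, class_code: int) -> list[int]:
        return [pid for pid, code, _ in self.patches if code == class_code]


@dataclass
class AdjacencyTable:
    """Double-count adjacency matrix g[i][k] between class codes.

    Every orthogonal pair of non-nodata cells contributes twice, once from
    each side, so ``g`` is symmetric and its total is 2× the pair count.
    """

    codes: tuple[int, ...]
    g: np.ndarray  # square, order matches codes

    def __post_init__(self) -> None:
        self._index = {c: i for i, c in enumerate(self.codes)}

    def like(self, code: int) -> int:
        i = self._index[code]
        return int(self.g[i, i])

    def total_for(self, code: int) -> int:
        return int(self.g[self._index[code]].sum())


# ---------------------------------------------------------------------------
# labeling


def label_grid(
    grid: np.ndarray, nodata_code: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """4-connected per-class labeling of an integer grid.

    Returns ``(labels, patch_classes, patch_areas)`` with labels 1..n
    contiguous, 0 on nodata; ``patch_classes[i-1]``/``patch_areas[i-1]``
    describe patch i.
    """
    grid = np.asarray(grid)
    labels = np.zeros(grid.shape, dtype=np.int32)
    classes: list[int] = []
    areas: list[int] = []
    offset = 0
    for code in np.unique(grid):
        code = int(code)
        if code == nodata_code:
            continue
        mask = grid == code
        lab, n = ndimage.label(mask, structure=FOUR_CONN)
        if n == 0:
            continue
        labels[mask] = lab[mask] + offset
        counts = np.bincount(lab[mask], minlength=n + 1)[1:]
        classes.extend([code] * n)
        areas.extend(int(a) for a in counts)
        offset += n
    return labels, np.asarray(classes, dtype=int), np.asarray(areas, dtype=int)


def label_patches(raster: CategoricalRaster) -> PatchSet:
    """Label 4-connected same-class patches; nodata cells stay unlabeled."""
    if not raster.valid_mask.any():
        raise RasterValidationError("cannot label an all-nodata raster")
    labels, classes, areas = label_grid(raster.grid, raster.legend.nodata_code)
    patches = [
        (i + 1, int(classes[i]), int(areas[i])) for i in range(len(classes))
    ]
    return PatchSet(
        patch_id_grid=labels, patches=patches, pixel_size_m=raster.pixel_size_m
    )


# ---------------------------------------------------------------------------
# adjacencies


def adjacency_matrix(
    grid: np.ndarray, nodata_code: int, codes: tuple[int, ...] | None = None
) -> tuple[tuple[int, ...], np.ndarray]:
    """Double-count orthogonal adjacency counts between class codes.

    Pairs touching a nodata cell are excluded.  Returns ``(codes, g)``.
    """
    grid = np.asarray(grid)
    if codes is None:
        present = np.unique(grid)
        codes = tuple(int(c) for c in present if c != nodata_code)
    index = {c: i for i, c in enumerate(codes)}
    m = len(codes)
    g = np.zeros((m, m), dtype=np.int64)
    if m == 0:
        return codes, g

    lut_size = int(grid.max(initial=0)) + 2
    lut = np.full(lut_size, -1, dtype=np.int64)
    for c, i in index.items():
        if 0 <= c < lut_size:
            lut[c] = i

    def accumulate(a: np.ndarray, b: np.ndarray) -> None:
        ia, ib = lut[a.ravel()], lut[b.ravel()]
        ok = (ia >= 0) & (ib >= 0)
        ia, ib = ia[ok], ib[ok]
        # double-count: once from each participating cell
        np.add.at(g, (ia, ib), 1)
        np.add.at(g, (ib, ia), 1)

    if grid.shape[1] > 1:
        accumulate(grid[:, :-1], grid[:, 1:])
    if grid.shape[0] > 1:
        accumulate(grid[:-1, :], grid[1:, :])
    return codes, g


def adjacency_counts(raster: CategoricalRaster) -> AdjacencyTable:
    """Adjacency table over all legend classes present in the raster."""
    codes, g = adjacency_matrix(raster.grid, raster.legend.nodata_code)
    return AdjacencyTable(codes=codes, g=g)


# ---------------------------------------------------------------------------
# CONTIG


def contig_values(labels: np.ndarray, areas: np.ndarray) -> np.ndarray:
    """CONTIG for every patch in a label grid, vectorised over patches.

    ``c_r`` for a pixel counts template weights only over neighbours in the
    *same patch* — a diagonal same-class cell from another patch does not
    contribute.  Implemented with shifted label comparisons so the cost is
    independent of patch count.
    """
    labels = np.asarray(labels)
    n = len(areas)
    if n == 0:
        return np.zeros(0)
    # per-pixel template sum over same-patch neighbours (centre weight 1)
    c = np.ones(labels.shape)
    offsets = [
        (dr, dc)
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dr, dc) != (0, 0)
    ]
    for dr, dc in offsets:
        w = CONTIG_TEMPLATE[dr + 1, dc + 1]
        shifted = np.full(labels.shape, 0, dtype=labels.dtype)
        src = (
            slice(max(dr, 0), labels.shape[0] + min(dr, 0)),
            slice(max(dc, 0), labels.shape[1] + min(dc, 0)),
        )
        dst = (
            slice(max(-dr, 0), labels.shape[0] + min(-dr, 0)),
            slice(max(-dc, 0), labels.shape[1] + min(-dc, 0)),
        )
        shifted[dst] = labels[src]
        c += w * (shifted == labels)
    c[labels == 0] = 0.0
    sums = ndimage.sum_labels(c, labels, index=np.arange(1, n + 1))
    mean_c = sums / np.asarray(areas, dtype=float)
    return (mean_c - 1.0) / (CONTIG_V - 1.0)


def contig(patchset: PatchSet, patch_id: int) -> MetricValue:
    """Contiguity index of one patch; 0 for single pixels, in [0, 1]."""
    idx = patchset._index(patch_id)
    areas = np.asarray([a for _, _, a in patchset.patches])
    values = contig_values(patchset.patch_id_grid, areas)
    return MetricValue(
        name="CONTIG", scope=f"patch:{patch_id}", value=float(values[idx]), units="index"
    )


# ---------------------------------------------------------------------------
# PLADJ


def pladj(table: AdjacencyTable, class_code: int | None = None) -> MetricValue:
    """Percentage of like adjacencies for one class, or landscape-wide.

    A class with zero total adjacencies has undefined PLADJ → NaN value.
    """
    if class_code is None:
        total = table.g.sum()
        like = np.trace(table.g)
        value = 100.0 * like / total if total > 0 else float("nan")
        scope = LANDSCAPE
    else:
        if class_code not in table._index:
            value, scope = float("nan"), f"class:{class_code}"
            return MetricValue(name="PLADJ", scope=scope, value=value, units="%")
        row = table.total_for(class_code)
        value = 100.0 * table.like(class_code) / row if row > 0 else float("nan")
        scope = f"class:{class_code}"
    return MetricValue(name="PLADJ", scope=scope, value=value, units="%")


# ---------------------------------------------------------------------------
# PD


def patch_density(
    patchset_or_count, area_m2: float, per_100ha: bool = False
) -> MetricValue:
    """Patch density: ``n / A × 10,000`` → patches per hectare.

    ``per_100ha=True`` applies the FRAGSTATS convention (an extra ×100).
    """
    if area_m2 <= 0:
        raise ValueError(f"landscape area must be positive, got {area_m2}")
    n = (
        patchset_or_count.n_patches
        if isinstance(patchset_or_count, PatchSet)
        else int(patchset_or_count)
    )
    scale = 10_000.0 * (100.0 if per_100ha else 1.0)
    units = "patches/100ha" if per_100ha else "patches/ha"
    return MetricValue(
        name="PD", scope=LANDSCAPE, value=n / area_m2 * scale, units=units
    )


# ---------------------------------------------------------------------------
# SHEI


def shei_value(
    grid: np.ndarray, nodata_code: int, subset: tuple[int, ...] | None = None
) -> float:
    """Shannon evenness of class proportions, normalised by ln m.

    With a *subset*, proportions are taken among subset-class cells only
    (species evenness within mangrove, say).  m counts classes actually
    present.  Conventions: m = 1 → 0; no counted cells → NaN.
    """
    grid = np.asarray(grid)
    valid = grid != nodata_code
    if subset is not None:
        valid &= np.isin(grid, np.asarray(subset))
    values = grid[valid]
    if values.size == 0:
        return float("nan")
    _, counts = np.unique(values, return_counts=True)
    m = len(counts)
    if m <= 1:
        return 0.0
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum() / np.log(m))


def shei(
    raster: CategoricalRaster, subset: tuple[int, ...] | None = None
) -> MetricValue:
    value = shei_value(raster.grid, raster.legend.nodata_code, subset)
    return MetricValue(name="SHEI", scope=LANDSCAPE, value=value, units="index")
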