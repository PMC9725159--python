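"""Synthetic inputs with the statistical structure the pipeline assumes.

No imagery ships with the method, so testing needs stand-ins for three
things: clumped multi-class land-cover maps, multi-date series showing
seaward mangrove expansion and interior fragmentation (conversion to
shrimp ponds), and labeled sample sets realising a given confusion matrix.

The landscape generator is a neutral-landscape construction: a Gaussian
random field, smoothed by an amount controlled by ``clumping`` and cut at
the quantiles of the requested class proportions.  ``clumping = 0`` gives
an i.i.d. random field; higher clumping gives larger, more aggregated
patches (higher PLADJ).  All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .accuracy_assessment import ConfusionMatrix
from .raster_io import CategoricalRaster, Legend

__all__ = [
    "LandscapeSpec",
    "SeriesSpec",
    "generate_landscape",
    "generate_series",
    "samples_from_confusion",
]

# smoothing radius (pixels) at clumping = 1; linear in clumping
_MAX_SIGMA = 4.0


@dataclass(frozen=True)
class LandscapeSpec:
    """Specification of one synthetic categorical landscape.

    ``mangrove_codes`` marks which class codes count as mangrove in the
    emitted legend; by default all but the last code (the last plays the
    non-mangrove matrix: aquaculture / settlement).
    """

    n_rows: int = 100
    n_cols: int = 100
    class_codes: tuple[int, ...] = (1, 2, 3, 4, 5)
    class_proportions: tuple[float, ...] = (0.25, 0.2, 0.15, 0.1, 0.3)
    clumping: float = 0.6
    pixel_size_m: float = 1.5
    seed: int = 0
    mangrove_codes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 3 or self.n_cols < 3:
            raise ValueError(f"grid too small: {self.n_rows}×{self.n_cols} (< 3×3)")
        if len(self.class_codes) != len(self.class_proportions):
            raise ValueError("class_codes and class_proportions lengths differ")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError(
                f"class proportions must sum to 1, got {sum(self.class_proportions)}"
            )
        if any(p < 0 for p in self.class_proportions):
            raise ValueError("class proportions must be non-negative")
        if not 0.0 <= self.clumping <= 1.0:
            raise ValueError(f"clumping must be in [0, 1], got {self.clumping}")
        if 0 in self.class_codes:
            raise ValueError("class code 0 is reserved for nodata")

    def effective_mangrove(self) -> tuple[int, ...]:
        if self.mangrove_codes is not None:
            return tuple(self.mangrove_codes)
        return tuple(self.class_codes[:-1]) if len(self.class_codes) > 1 else tuple(
            self.class_codes
        )

    def make_legend(self) -> Legend:
        mangrove = set(self.effective_mangrove())
        return Legend(
            entries=tuple(
                (c, f"class_{c}", c in mangrove) for c in self.class_codes
            ),
            nodata_code=0,
        )


@dataclass(frozen=True)
class SeriesSpec:
    """Multi-date dynamics: frontier expansion and interior fragmentation.

    ``expansion_rate`` — fraction of the non-mangrove frontier (cells
    orthogonal to mangrove) converted to mangrove per step, emulating
    accretion planting; ``fragmentation_rate`` — fraction of mangrove
    patch-interior cells punched out per step, emulating conversion to
    shrimp ponds inside the forest.
    """

    base: LandscapeSpec = field(default_factory=LandscapeSpec)
    n_dates: int = 3
    expansion_rate: float = 0.1
    fragmentation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dates < 2:
            raise ValueError(f"a series needs >= 2 dates, got {self.n_dates}")
        for name in ("expansion_rate", "fragmentation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def generate_landscape(spec: LandscapeSpec) -> CategoricalRaster:
    """Smoothed-random-field landscape cut at class-proportion quantiles.

    Deterministic given ``spec.seed``; class proportions are exact up to
    quantile rounding (well within ±5 points on grids >= 100×100); higher
    clumping yields higher landscape PLADJ in expectation.
    """
    rng = np.random.default_rng(spec.seed)
    fld = rng.standard_normal((spec.n_rows, spec.n_cols))
    sigma = _MAX_SIGMA * spec.clumping
    if sigma > 0:
        fld = ndimage.gaussian_filter(fld, sigma=sigma, mode="wrap")
    # cut the field at the proportion quantiles: class k occupies the slab
    # between cumulative proportions
    cum = np.cumsum(spec.class_proportions)[:-1]
    edges = np.quantile(fld, cum) if len(cum) else np.empty(0)
    idx = np.searchsorted(edges, fld, side="right")
    codes = np.asarray(spec.class_codes, dtype=np.int32)
    grid = codes[idx]
    return CategoricalRaster(
        grid=grid,
        pixel_size_m=spec.pixel_size_m,
        legend=spec.make_legend(),
        crs_tag="synthetic",
    )


def _mangrove_mask(grid: np.ndarray, mangrove: tuple[int, ...]) -> np.ndarray:
    return np.isin(grid, np.asarray(mangrove))


def _orthogonal_neighbour_count(mask: np.ndarray) -> np.ndarray:
    kernel = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    return ndimage.convolve(mask.astype(np.int32), kernel, mode="constant", cval=0)


def _expand_step(
    grid: np.ndarray,
    mangrove: tuple[int, ...],
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Convert frontier non-mangrove cells (orthogonal to mangrove) to the
    mangrove code of a neighbouring cell — accretion-like growth."""
    mask = _mangrove_mask(grid, mangrove)
    frontier = (~mask) & (_orthogonal_neighbour_count(mask) > 0)
    candidates = np.flatnonzero(frontier.ravel())
    if candidates.size == 0 or rate == 0:
        return grid
    # the rate applies to the non-mangrove pool; only frontier cells are
    # eligible, so conversion is capped by the frontier size
    n_pool = int((~mask).sum())
    n_convert = min(candidates.size, math.ceil(rate * n_pool))
    chosen = rng.choice(candidates, size=n_convert, replace=False)
    out = grid.copy()
    nrows, ncols = grid.shape
    for flat in chosen:
        r, c = divmod(int(flat), ncols)
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and mask[rr, cc]:
                out[r, c] = grid[rr, cc]
                break
    return out


def _fragment_step(
    grid: np.ndarray,
    mangrove: tuple[int, ...],
    non_mangrove_code: int,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Punch out interior mangrove cells (4 same-class orthogonal
    neighbours), reassigning them to a non-mangrove code — pond conversion
    inside the forest."""
    if rate == 0:
        return grid
    interior = np.zeros(grid.shape, dtype=bool)
    for code in mangrove:
        mask = grid == code
        interior |= mask & (_orthogonal_neighbour_count(mask) == 4)
    candidates = np.flatnonzero(interior.ravel())
    if candidates.size == 0:
        return grid
    n_remove = min(candidates.size, math.ceil(rate * candidates.size))
    chosen = rng.choice(candidates, size=n_remove, replace=False)
    out = grid.copy()
    out.ravel()[chosen] = non_mangrove_code
    return out


def generate_series(spec: SeriesSpec) -> list[CategoricalRaster]:
    """Generate an ordered multi-date series from a base landscape.

    With ``fragmentation_rate = 0`` the mangrove cell count never
    decreases; with both rates zero all dates are identical.
    """
    base = generate_landscape(replace(spec.base, seed=spec.base.seed))
    legend = base.legend
    mangrove = tuple(legend.mangrove_codes)
    non_mangrove = [c for c in legend.codes if c not in mangrove]
    if spec.fragmentation_rate > 0 and not non_mangrove:
        raise ValueError("fragmentation needs at least one non-mangrove class")
    sink = non_mangrove[0] if non_mangrove else None
    rng = np.random.default_rng((spec.seed, 0xC0FFEE))
    rasters = [base]
    grid = base.grid
    for _ in range(spec.n_dates - 1):
        grid = _expand_step(grid, mangrove, spec.expansion_rate, rng)
        if sink is not None:
            grid = _fragment_step(
                grid, mangrove, sink, spec.fragmentation_rate, rng
            )
        rasters.append(
            CategoricalRaster(
                grid=grid.copy(),
                pixel_size_m=base.pixel_size_m,
                legend=legend,
                crs_tag=base.crs_tag,
            )
        )
    return rasters


def samples_from_confusion(matrix: ConfusionMatrix) -> list[tuple]:
    """Expand a count matrix into the multiset of (reference, predicted)
    label pairs it tabulates; re-tabulating the result recovers the matrix
    exactly, and the list length equals the matrix total."""
    counts = np.asarray(matrix.counts)
    if (counts < 0).any():
        raise ValueError("confusion counts must be non-negative")
    pairs: list[tuple] = []
    order = matrix.class_order
    for i, ref in enumerate(order):
        for j, pred in enumerate(order):
            pairs.extend([(ref, pred)] * int(counts[i, j]))
    return pairs
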