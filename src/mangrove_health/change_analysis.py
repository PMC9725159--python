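"""Multi-date change analysis: class areas, transitions, MHI change maps.

Change in health is computed on the classified MHI maps (post-
classification comparison): a cell is *improved* where its health class
rose between dates, *degraded* where it fell, *stable* otherwise.  Cells
nodata at either date are excluded from all tables and maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster_io import CategoricalRaster, RankRaster, require_aligned

__all__ = [
    "TransitionTable",
    "ChangeMap",
    "area_by_class",
    "transition_matrix",
    "mhi_change",
]

IMPROVED, STABLE, DEGRADED = 1, 0, -1
CHANGE_NODATA = -9


@dataclass
class TransitionTable:
    """Cell counts and hectares moving from class i (date 1) to j (date 2)."""

    counts: np.ndarray
    class_order: tuple[int, ...]
    pixel_size_m: float

    @property
    def hectares(self) -> np.ndarray:
        return self.counts * self.pixel_size_m**2 / 10_000.0

    def to_frame(self, hectares: bool = False) -> pd.DataFrame:
        data = self.hectares if hectares else self.counts
        return pd.DataFrame(
            data, index=list(self.class_order), columns=list(self.class_order)
        )


@dataclass
class ChangeMap:
    """Per-cell health-change category: improved / stable / degraded.

    ``grid`` holds +1 improved, 0 stable, −1 degraded, −9 nodata;
    ``delta`` is the raw class difference (diagnostic)."""

    grid: np.ndarray
    delta: np.ndarray
    pixel_size_m: float

    def counts(self) -> dict[str, int]:
        return {
            "improved": int((self.grid == IMPROVED).sum()),
            "stable": int((self.grid == STABLE).sum()),
            "degraded": int((self.grid == DEGRADED).sum()),
        }


def area_by_class(raster: CategoricalRaster) -> pd.Series:
    """Hectares per legend class: cells × pixel_size² / 10,000.

    Classes absent from the raster report 0 ha; the total over classes
    equals the total valid area.
    """
    cell_ha = raster.pixel_size_m**2 / 10_000.0
    out = {}
    for code in raster.legend.codes:
        out[code] = float((raster.grid == code).sum()) * cell_ha
    return pd.Series(out, name="hectares")


def transition_matrix(
    t1: CategoricalRaster, t2: CategoricalRaster
) -> TransitionTable:
    """Tabulate class transitions over jointly valid cells of two dates."""
    require_aligned(t1, t2, "transition rasters")
    if t1.legend.codes != t2.legend.codes:
        raise ValueError("transition rasters must share a legend")
    codes = t1.legend.codes
    index = {c: i for i, c in enumerate(codes)}
    both = t1.valid_mask & t2.valid_mask
    a = t1.grid[both]
    b = t2.grid[both]
    counts = np.zeros((len(codes), len(codes)), dtype=np.int64)
    lut = np.full(max(codes) + 1, -1, dtype=np.int64)
    for c, i in index.items():
        lut[c] = i
    np.add.at(counts, (lut[a], lut[b]), 1)
    return TransitionTable(
        counts=counts, class_order=codes, pixel_size_m=t1.pixel_size_m
    )


def mhi_change(c1: RankRaster, c2: RankRaster) -> ChangeMap:
    """Compare two classified MHI maps cell-wise.

    Antisymmetric under swapping dates: improved and degraded exchange.
    """
    require_aligned(c1, c2, "MHI class rasters")
    both = c1.valid_mask & c2.valid_mask
    delta = np.where(both, c2.grid.astype(int) - c1.grid.astype(int), 0)
    grid = np.full(c1.shape, CHANGE_NODATA, dtype=np.int8)
    grid[both & (delta > 0)] = IMPROVED
    grid[both & (delta == 0)] = STABLE
    grid[both & (delta < 0)] = DEGRADED
    return ChangeMap(grid=grid, delta=delta, pixel_size_m=c1.pixel_size_m)
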