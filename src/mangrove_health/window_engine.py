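"""Moving-window rasterisation of the whole-extent metrics.

Every interior cell receives the metric value of the ``size × size`` crop
centred on it (5×5 by default), so window output and whole-extent
computation on the crop are the same thing by construction.  Class-scoped
metrics (CONTIG, PLADJ, PD) are computed for the mangrove super-class: all
``is_mangrove`` legend codes merged into one class, so the factor maps are
single health layers rather than per-species layers.  SHEI keeps the
individual mangrove codes and measures species evenness within the window.
A species-richness statistic (count of distinct mangrove codes in the
window) is also available; it backs the diversity ranking rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .patch_metrics import (
    adjacency_matrix,
    contig_values,
    label_grid,
    shei_value,
)
from .raster_io import CategoricalRaster, FactorRaster, RasterValidationError

__all__ = ["WindowSpec", "windowed_metric", "factor_stack", "window_value", "FACTOR_NAMES"]

METRICS = ("CONTIG", "PLADJ", "PD", "SHEI", "RICHNESS")

#: factor-map naming: metric -> health factor it maps (canopy, fragmentation,
#: density, diversity)
FACTOR_NAMES = {
    "CONTIG": "canopy_width",
    "PLADJ": "fragmentation",
    "PD": "density",
    "SHEI": "diversity",
    "RICHNESS": "species_richness",
}


@dataclass(frozen=True)
class WindowSpec:
    """Moving-window configuration.

    ``nodata_policy`` is the minimum fraction of valid (non-nodata) cells a
    window must contain to get a value; ``edge_policy`` is ``"nodata"``
    (border cells get nodata, the default) or ``"shrink"`` (the window is
    clipped at the raster edge).
    """

    size: int = 5
    metric: str = "PLADJ"
    focal_classes: tuple[int, ...] = ()
    edge_policy: str = "nodata"
    nodata_policy: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError(f"window size must be odd and >= 3, got {self.size}")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; choose from {METRICS}")
        if self.edge_policy not in ("nodata", "shrink"):
            raise ValueError(f"edge_policy must be 'nodata' or 'shrink'")
        if not 0.0 <= self.nodata_policy <= 1.0:
            raise ValueError("nodata_policy must be in [0, 1]")


def window_value(
    crop: np.ndarray,
    metric: str,
    focal: tuple[int, ...],
    nodata_code: int,
    pixel_size_m: float,
) -> float:
    """Whole-extent *metric* of one window crop.

    The defining property of the engine: :func:`windowed_metric` returns
    exactly this value at each centre cell.
    """
    crop = np.asarray(crop)
    valid = crop != nodata_code
    if not valid.any():
        return float("nan")

    if metric == "SHEI":
        return shei_value(crop, nodata_code, subset=focal if focal else None)

    if metric == "RICHNESS":
        present = np.unique(crop[valid])
        if focal:
            return float(np.isin(present, np.asarray(focal)).sum())
        return float(len(present))

    # class-scoped metrics: merge focal codes into one super-class
    if focal:
        merged_code = int(max(int(crop.max()), max(focal))) + 1
        work = np.where(np.isin(crop, np.asarray(focal)), merged_code, crop)
        target = merged_code
        focal_mask = work == merged_code
    else:
        work, target, focal_mask = crop, None, valid

    if metric == "PLADJ":
        codes, g = adjacency_matrix(work, nodata_code)
        if target is None:  # landscape scope
            total = g.sum()
            return 100.0 * np.trace(g) / total if total > 0 else float("nan")
        if target not in codes:
            return float("nan")
        i = codes.index(target)
        row = g[i].sum()
        return 100.0 * g[i, i] / row if row > 0 else float("nan")

    if metric == "PD":
        area_m2 = float(valid.sum()) * pixel_size_m**2
        if target is None:
            _, _, areas = label_grid(work, nodata_code)
            n = len(areas)
        else:
            labels, classes, areas = label_grid(
                np.where(focal_mask, work, nodata_code), nodata_code
            )
            n = len(areas)
        return n / area_m2 * 10_000.0

    if metric == "CONTIG":
        sub = np.where(focal_mask, work, nodata_code)
        labels, classes, areas = label_grid(sub, nodata_code)
        if len(areas) == 0:
            return float("nan")
        values = contig_values(labels, areas)
        # one canopy value per window: area-weighted mean over patches
        return float(np.average(values, weights=areas))

    raise ValueError(f"unknown metric {metric!r}")  # pragma: no cover


def windowed_metric(raster: CategoricalRaster, spec: WindowSpec) -> FactorRaster:
    """Slide the window over *raster*, returning values to centre cells.

    Output nodata (NaN) wherever the centre cell is nodata, the window has
    too few valid cells, or the metric is undefined on the crop; with
    ``edge_policy="nodata"`` also on the half-window border.
    """
    nrows, ncols = raster.shape
    if nrows < spec.size or ncols < spec.size:
        raise RasterValidationError(
            f"window {spec.size}×{spec.size} larger than raster {raster.shape}"
        )
    half = spec.size // 2
    grid = raster.grid
    nodata = raster.legend.nodata_code
    out = np.full(raster.shape, np.nan)
    if spec.edge_policy == "nodata":
        row_range = range(half, nrows - half)
        col_range = range(half, ncols - half)
    else:
        row_range = range(nrows)
        col_range = range(ncols)
    min_valid = spec.nodata_policy * spec.size * spec.size
    for r in row_range:
        r0, r1 = max(r - half, 0), min(r + half + 1, nrows)
        for c in col_range:
            if grid[r, c] == nodata:
                continue
            crop = grid[r0:r1, max(c - half, 0) : min(c + half + 1, ncols)]
            if (crop != nodata).sum() < min_valid:
                continue
            out[r, c] = window_value(
                crop, spec.metric, spec.focal_classes, nodata, raster.pixel_size_m
            )
    return FactorRaster(
        grid=out,
        pixel_size_m=raster.pixel_size_m,
        factor_name=FACTOR_NAMES[spec.metric],
        crs_tag=raster.crs_tag,
    )


def factor_stack(
    raster: CategoricalRaster,
    specs: list[WindowSpec] | None = None,
    size: int = 5,
) -> list[FactorRaster]:
    """Compute the aligned factor maps for one date.

    Default stack: CONTIG → canopy width, PLADJ → fragmentation,
    PD → density, SHEI → diversity, all over the mangrove classes.
    """
    if specs is None:
        focal = raster.legend.mangrove_codes
        specs = [
            WindowSpec(size=size, metric=m, focal_classes=focal)
            for m in ("CONTIG", "PLADJ", "PD", "SHEI")
        ]
    if not specs:
        raise ValueError("specs must be non-empty")
    return [windowed_metric(raster, spec) for spec in specs]
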