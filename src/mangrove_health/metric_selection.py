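"""Pairwise Pearson screening of candidate metric layers.

Candidate factor maps are correlated pairwise — and against a numeric
encoding of the classification layer ("CLS") — to check which metrics track
the mangrove distribution.  The CLS encoding for correlation is integer
class codes over mangrove classes with all other classes set to 0 (the
choice is configurable and recorded in output metadata).  Cells nodata in
either layer of a pair are dropped pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster_io import CategoricalRaster, FactorRaster, require_aligned

__all__ = [
    "CorrelationMatrix",
    "encode_cls",
    "pearson_matrix",
    "r_squared",
    "export_heatmap_table",
    "read_heatmap_table",
]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix over named layers with unit diagonal."""

    labels: tuple[str, ...]
    r: np.ndarray
    n: np.ndarray  # jointly valid cell counts per pair

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=list(self.labels), columns=list(self.labels))


def encode_cls(
    raster: CategoricalRaster, mangrove_only: bool = True
) -> FactorRaster:
    """Encode the classification for correlation: mangrove class codes kept,
    everything else 0; nodata stays nodata."""
    grid = raster.grid.astype(float)
    if mangrove_only:
        keep = np.isin(raster.grid, np.asarray(raster.legend.mangrove_codes))
        grid = np.where(keep, grid, 0.0)
    grid[raster.nodata_mask] = np.nan
    return FactorRaster(
        grid=grid,
        pixel_size_m=raster.pixel_size_m,
        factor_name="CLS",
        crs_tag=raster.crs_tag,
    )


def _pairwise_r(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >= 3 jointly valid cells, got {n}")
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return float("nan"), n  # jointly constant pair: undefined
    r = float(np.corrcoef(xv, yv)[0, 1])
    return r, n


def pearson_matrix(layers: list[FactorRaster], labels=None) -> CorrelationMatrix:
    """Pairwise Pearson r over cells valid in both layers of each pair."""
    if len(layers) < 2:
        raise ValueError("need at least two layers")
    for other in layers[1:]:
        require_aligned(layers[0], other, "correlation layers")
    if labels is None:
        labels = tuple(
            lyr.factor_name or f"layer_{i}" for i, lyr in enumerate(layers)
        )
    labels = tuple(labels)
    m = len(layers)
    r = np.eye(m)
    n = np.zeros((m, m), dtype=np.int64)
    flats = [lyr.grid.ravel() for lyr in layers]
    for i in range(m):
        n[i, i] = int((~np.isnan(flats[i])).sum())
        for j in range(i + 1, m):
            rij, nij = _pairwise_r(flats[i], flats[j])
            r[i, j] = r[j, i] = rij
            n[i, j] = n[j, i] = nij
    return CorrelationMatrix(labels=labels, r=r, n=n)


def r_squared(metric: FactorRaster, cls: FactorRaster) -> float:
    """Coefficient of determination of the simple linear fit metric ~ CLS
    (equals the squared Pearson r)."""
    require_aligned(metric, cls, "regression layers")
    r, _ = _pairwise_r(metric.grid.ravel(), cls.grid.ravel())
    return r * r


def export_heatmap_table(matrix: CorrelationMatrix, path) -> str:
    """Write the labeled coefficient matrix as CSV (rendering is left to
    the caller, e.g. seaborn.heatmap on the re-read frame)."""
    matrix.to_frame().to_csv(path, float_format="%.15g")
    return str(path)


def read_heatmap_table(path) -> CorrelationMatrix:
    df = pd.read_csv(path, index_col=0)
    return CorrelationMatrix(
        labels=tuple(df.index), r=df.to_numpy(), n=np.zeros(df.shape, dtype=np.int64)
    )
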