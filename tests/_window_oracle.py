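"""Crop-level oracle for the moving-window engine.

Computes a window's metric from the whole-extent patch_metrics module on
the crop, bypassing the engine's own per-window code path, so the two
routes check each other.
"""

from __future__ import annotations

import numpy as np

from mangrove_health.patch_metrics import (
    adjacency_counts,
    contig_values,
    label_grid,
    pladj,
    shei_value,
)
from mangrove_health.raster_io import CategoricalRaster, Legend


def crop_metric(crop, metric, focal, nodata, pixel):
    crop = np.asarray(crop)
    valid = crop != nodata
    if metric == "SHEI":
        return shei_value(crop, nodata, subset=focal)
    merged = max(int(crop.max()), max(focal)) + 1
    work = np.where(np.isin(crop, np.asarray(focal)), merged, crop)
    if metric == "PLADJ":
        legend_entries = tuple(
            (int(c), str(c), False) for c in np.unique(work) if c != nodata
        )
        if not legend_entries:
            return float("nan")
        raster = CategoricalRaster(
            work.astype(np.int32), 1.0, Legend(legend_entries, nodata)
        )
        return pladj(adjacency_counts(raster), merged).value
    if metric == "PD":
        sub = np.where(work == merged, merged, nodata)
        _, _, areas = label_grid(sub, nodata)
        return len(areas) / (valid.sum() * pixel**2) * 10_000.0
    if metric == "CONTIG":
        sub = np.where(work == merged, merged, nodata)
        labels, _, areas = label_grid(sub, nodata)
        if len(areas) == 0:
            return float("nan")
        return float(np.average(contig_values(labels, areas), weights=areas))
    raise ValueError(metric)
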