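"""End-to-end pipeline: classified rasters in, health maps and tables out.

One config drives the whole flow per date — factor stack → factor ranks →
MHI surface → classified health map — then across consecutive dates the
transition matrix and the health-change map.  Everything is written under
the configured output directory together with a manifest (output paths +
SHA-256 checksums) and a provenance record (echoed config, config hash,
package and library versions), so a run is reproducible from its own
output directory.  The pipeline itself is deterministic; the seed only
feeds the synthetic generator when inputs are simulated.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .change_analysis import area_by_class, mhi_change, transition_matrix
from .health_scoring import (
    DEFAULT_MHI_BINS,
    MembershipTable,
    PairwiseMatrix,
    RankThresholds,
    WeightVector,
    ahp_weights,
    classify_mhi,
    default_thresholds,
    mhi_map,
    rank_factor,
    thresholds_from_quantiles,
    weights_from_membership,
)
from .metric_selection import encode_cls, export_heatmap_table, pearson_matrix
from .raster_io import CategoricalRaster, Legend, read_categorical, write_raster
from .window_engine import WindowSpec, windowed_metric

logger = logging.getLogger("mangrove_health")

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError", "resolve_weights"]

#: factor order used everywhere downstream: names and source metrics
FACTOR_ORDER = ("canopy_width", "fragmentation", "density", "diversity")
FACTOR_METRIC = {
    "canopy_width": "CONTIG",
    "fragmentation": "PLADJ",
    "density": "PD",
    "diversity": "SHEI",
}
#: factor whose ranking runs on the species-richness window statistic
RICHNESS_RANKED = "diversity"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`."""

    legend: Legend
    dates: tuple[tuple[str, str], ...]  # (date label, raster path), ordered
    pixel_size_m: float = 1.5
    window_size: int = 5
    nodata_policy: float = 0.0
    weights_source: dict = field(default_factory=dict)
    threshold_overrides: dict = field(default_factory=dict)
    mhi_bins: tuple[float, ...] = DEFAULT_MHI_BINS
    output_dir: str = "mhi_output"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dates) < 1:
            raise ValueError("config needs at least one dated raster")
        labels = [d for d, _ in self.dates]
        if labels != sorted(labels):
            raise ValueError(f"dates must be ordered, got {labels}")
        for label, path in self.dates:
            if not Path(path).exists():
                raise FileNotFoundError(f"date {label}: raster not found: {path}")

    @classmethod
    def from_dict(cls, cfg: dict, base_dir: str | Path = ".") -> "PipelineConfig":
        base = Path(base_dir)
        legend = Legend.from_dicts(
            cfg["legend"]["classes"], cfg["legend"].get("nodata", 0)
        )
        dates = tuple(
            (str(d["name"]), str(base / d["path"])) for d in cfg["dates"]
        )
        window = cfg.get("window", {})
        return cls(
            legend=legend,
            dates=dates,
            pixel_size_m=float(cfg.get("pixel_size_m", 1.5)),
            window_size=int(window.get("size", 5)),
            nodata_policy=float(window.get("nodata_policy", 0.0)),
            weights_source=cfg.get("weights", {}),
            threshold_overrides=cfg.get("thresholds", {}),
            mhi_bins=tuple(cfg.get("mhi_bins", DEFAULT_MHI_BINS)),
            output_dir=str(base / cfg.get("output_dir", "mhi_output")),
            seed=int(cfg.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls.from_dict(cfg, base_dir=path.parent)


def resolve_weights(source: dict) -> WeightVector:
    """Resolve factor weights with precedence: explicit > pairwise matrix
    (AHP) > membership table (normalised scores) > published reference."""
    names = tuple(source.get("factor_names", FACTOR_ORDER))
    if "explicit" in source:
        w = np.asarray(source["explicit"], dtype=float)
        return WeightVector(w=w / w.sum(), factor_names=names)
    if "pairwise" in source:
        pm = PairwiseMatrix(
            m=np.asarray(source["pairwise"], dtype=float),
            factor_names=names,
            scale_max=float(source.get("scale_max", 4.0)),
        )
        return ahp_weights(pm)
    if "membership" in source:
        mt = MembershipTable(
            R=np.asarray(source["membership"], dtype=float),
            factor_names=names,
        )
        scores = weights_from_membership(mt)
        return WeightVector(w=scores / scores.sum(), factor_names=names)
    from .health_scoring import REFERENCE_WEIGHTS

    return WeightVector(w=np.asarray(REFERENCE_WEIGHTS), factor_names=FACTOR_ORDER)


def _thresholds_for(
    name: str, overrides: dict, density_factor
) -> RankThresholds:
    if name in overrides:
        iv = tuple(tuple(x) for x in overrides[name]["intervals"])
        return RankThresholds(name, tuple((float(a), float(b), int(r)) for a, b, r in iv))
    defaults = default_thresholds()
    if name in defaults:
        return defaults[name]
    if name == "density":
        return thresholds_from_quantiles(density_factor)
    raise KeyError(name)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full flow; returns the manifest written to the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"dates": {}, "change": {}, "files": {}}
    t_start = time.time()

    def stage(name):
        logger.info("stage %s", name)
        return name

    def record(key: str, path: Path) -> str:
        manifest["files"][str(path.relative_to(out))] = _sha256(path)
        return str(path)

    per_date_class: dict[str, object] = {}
    per_date_rasters = {}
    for label, path in config.dates:
        current = stage(f"read[{label}]")
        try:
            raster = read_categorical(
                path, config.legend, pixel_size_m=config.pixel_size_m
            )
            per_date_rasters[label] = raster
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {current} failed: {exc}") from exc

    weights = resolve_weights(config.weights_source)

    for label, raster in per_date_rasters.items():
        date_entry: dict = {"factors": {}, "ranks": {}}
        focal = raster.legend.mangrove_codes
        factors = {}
        current = stage(f"factors[{label}]")
        try:
            for fname in FACTOR_ORDER:
                spec = WindowSpec(
                    size=config.window_size,
                    metric=FACTOR_METRIC[fname],
                    focal_classes=focal,
                    nodata_policy=config.nodata_policy,
                )
                factors[fname] = windowed_metric(raster, spec)
            richness = windowed_metric(
                raster,
                WindowSpec(
                    size=config.window_size,
                    metric="RICHNESS",
                    focal_classes=focal,
                    nodata_policy=config.nodata_policy,
                ),
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {current} failed: {exc}") from exc
        for fname, fr in {**factors, "species_richness": richness}.items():
            p = out / f"{label}_factor_{fname}.tif"
            write_raster(fr, p)
            date_entry["factors"][fname] = record(f"factor_{fname}", p)

        current = stage(f"correlate[{label}]")
        try:
            layers = [factors[f] for f in FACTOR_ORDER] + [encode_cls(raster)]
            corr = pearson_matrix(layers)
            p = out / f"{label}_correlation.csv"
            export_heatmap_table(corr, p)
            date_entry["correlation"] = record("correlation", p)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {current} failed: {exc}") from exc

        current = stage(f"rank[{label}]")
        try:
            ranks = []
            for fname in FACTOR_ORDER:
                if fname == RICHNESS_RANKED:
                    source, tname = richness, "species_richness"
                else:
                    source, tname = factors[fname], fname
                th = _thresholds_for(
                    tname, config.threshold_overrides, factors["density"]
                )
                rr = rank_factor(source, th)
                ranks.append(rr)
                p = out / f"{label}_rank_{fname}.tif"
                write_raster(rr, p)
                date_entry["ranks"][fname] = record(f"rank_{fname}", p)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {current} failed: {exc}") from exc

        current = stage(f"mhi[{label}]")
        try:
            mhi = mhi_map(ranks, weights)
            classified = classify_mhi(mhi, config.mhi_bins)
            p = out / f"{label}_mhi.tif"
            write_raster(mhi, p)
            date_entry["mhi"] = record("mhi", p)
            p = out / f"{label}_mhi_class.tif"
            write_raster(classified, p)
            date_entry["mhi_class"] = record("mhi_class", p)
            per_date_class[label] = classified
            valid = mhi.grid[mhi.valid_mask]
            date_entry["mean_mhi"] = float(valid.mean()) if valid.size else None
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {current} failed: {exc}") from exc

        areas = area_by_class(raster)
        p = out / f"{label}_area_by_class.csv"
        areas.to_csv(p, header=True)
        date_entry["areas"] = record("areas", p)
        manifest["dates"][label] = date_entry

    labels = [lab for lab, _ in config.dates]
    for a, b in zip(labels, labels[1:]):
        current = stage(f"change[{a}->{b}]")
        try:
            tt = transition_matrix(per_date_rasters[a], per_date_rasters[b])
            p = out / f"transition_{a}_{b}.csv"
            tt.to_frame(hectares=True).to_csv(p)
            entry = {"transition": record("transition", p)}
            cm = mhi_change(per_date_class[a], per_date_class[b])
            entry["change_counts"] = cm.counts()
            delta = out / f"mhi_change_{a}_{b}.csv"
            pd.DataFrame(cm.grid).to_csv(delta, index=False, header=False)
            entry["change_map"] = record("change_map", delta)
            manifest["change"][f"{a}->{b}"] = entry
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {current} failed: {exc}") from exc

    cfg_echo = {
        "legend": config.legend.to_dicts(),
        "dates": list(map(list, config.dates)),
        "pixel_size_m": config.pixel_size_m,
        "window_size": config.window_size,
        "weights": {
            "factor_names": list(weights.factor_names),
            "w": [float(x) for x in weights.w],
        },
        "mhi_bins": list(config.mhi_bins),
        "seed": config.seed,
    }
    manifest["provenance"] = {
        "package_version": __version__,
        "numpy": np.__version__,
        "config": cfg_echo,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_echo, sort_keys=True).encode()
        ).hexdigest(),
        "elapsed_s": round(time.time() - t_start, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
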