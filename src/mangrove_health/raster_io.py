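"""Raster containers and single-band TIFF I/O.

Three raster kinds flow through the pipeline:

* :class:`CategoricalRaster` — integer land-cover codes plus a legend;
* :class:`FactorRaster` — a continuous metric surface (one health factor);
* :class:`RankRaster` — integer ranks 1..4 (factor ranks or MHI classes).

All share a grid convention: row-major, row 0 = northernmost, 0-based
``(row, col)`` indexing.  Pixel size is carried in metres; areas are
``cell_count * pixel_size_m**2`` and hectares are m²/10,000.  The CRS is an
opaque tag, never interpreted.

Files are single-band TIFFs.  Pixel size, nodata, kind and the CRS tag are
stored as JSON in the ImageDescription tag; nodata is mirrored in the
GDAL_NODATA tag (42113) so GIS software picks it up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "Legend",
    "CategoricalRaster",
    "FactorRaster",
    "RankRaster",
    "RasterFormatError",
    "RasterValidationError",
    "read_categorical",
    "read_factor",
    "read_rank",
    "write_raster",
    "assert_aligned",
]

#: ranks used by factor ranking and MHI classification
RANKS = (1, 2, 3, 4)

# GDAL's ad-hoc nodata TIFF tag, written as ASCII
_GDAL_NODATA_TAG = 42113


class RasterFormatError(ValueError):
    """File on disk is not a raster this package can read."""


class RasterValidationError(ValueError):
    """Raster content violates its contract (unknown codes, bad shape...)."""


@dataclass(frozen=True)
class Legend:
    """Class-code legend: ``(code, name, is_mangrove)`` entries plus nodata.

    Codes must be unique and distinct from ``nodata_code``.
    """

    entries: tuple[tuple[int, str, bool], ...]
    nodata_code: int = 0

    def __post_init__(self) -> None:
        if not self.entries:
            raise RasterValidationError("legend needs at least one entry")
        codes = [int(c) for c, _, _ in self.entries]
        if len(set(codes)) != len(codes):
            raise RasterValidationError(f"duplicate legend codes: {codes}")
        if self.nodata_code in codes:
            raise RasterValidationError(
                f"nodata code {self.nodata_code} collides with a class code"
            )

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(int(c) for c, _, _ in self.entries)

    @property
    def mangrove_codes(self) -> tuple[int, ...]:
        return tuple(int(c) for c, _, m in self.entries if m)

    def name_of(self, code: int) -> str:
        for c, name, _ in self.entries:
            if c == code:
                return name
        raise KeyError(code)

    @classmethod
    def from_dicts(cls, rows, nodata_code: int = 0) -> "Legend":
        """Build from config-style dicts with keys code/name/is_mangrove."""
        entries = tuple(
            (int(r["code"]), str(r["name"]), bool(r.get("is_mangrove", False)))
            for r in rows
        )
        return cls(entries=entries, nodata_code=int(nodata_code))

    def to_dicts(self):
        return [
            {"code": c, "name": n, "is_mangrove": m} for c, n, m in self.entries
        ]


@dataclass
class CategoricalRaster:
    """Integer class-code grid with pixel geometry and a legend."""

    grid: np.ndarray
    pixel_size_m: float
    legend: Legend
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise RasterValidationError("grid must be 2-D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise RasterFormatError(
                f"categorical raster band must be integer, got {self.grid.dtype}"
            )
        if self.pixel_size_m <= 0:
            raise RasterValidationError("pixel_size_m must be positive")
        allowed = set(self.legend.codes) | {self.legend.nodata_code}
        present = set(np.unique(self.grid).tolist())
        unknown = sorted(present - allowed)
        if unknown:
            raise RasterValidationError(
                f"codes not in legend: {unknown} (legend codes {sorted(allowed)})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.grid == self.legend.nodata_code

    @property
    def valid_mask(self) -> np.ndarray:
        return self.grid != self.legend.nodata_code


@dataclass
class FactorRaster:
    """Continuous metric surface aligned to its source categorical raster.

    ``grid`` is float; nodata cells are NaN (``nodata_mask`` mirrors them).
    """

    grid: np.ndarray
    pixel_size_m: float
    factor_name: str = ""
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise RasterValidationError("grid must be 2-D")
        if self.pixel_size_m <= 0:
            raise RasterValidationError("pixel_size_m must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.grid)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.grid)


@dataclass
class RankRaster:
    """Integer raster with values in {1,2,3,4}; 0 encodes nodata."""

    grid: np.ndarray
    pixel_size_m: float
    nodata_code: int = 0
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise RasterFormatError("rank raster band must be integer")
        allowed = set(RANKS) | {self.nodata_code}
        present = set(np.unique(self.grid).tolist())
        bad = sorted(present - allowed)
        if bad:
            raise RasterValidationError(f"rank values outside {{1..4}}: {bad}")
        if self.pixel_size_m <= 0:
            raise RasterValidationError("pixel_size_m must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.grid == self.nodata_code

    @property
    def valid_mask(self) -> np.ndarray:
        return self.grid != self.nodata_code


# ---------------------------------------------------------------------------
# file I/O


def _metadata_for(raster) -> dict:
    meta = {"pixel_size_m": float(raster.pixel_size_m), "crs_tag": raster.crs_tag}
    if isinstance(raster, CategoricalRaster):
        meta["kind"] = "categorical"
        meta["nodata"] = raster.legend.nodata_code
    elif isinstance(raster, RankRaster):
        meta["kind"] = "rank"
        meta["nodata"] = raster.nodata_code
    elif isinstance(raster, FactorRaster):
        meta["kind"] = "factor"
        meta["nodata"] = "nan"
        meta["factor_name"] = raster.factor_name
    else:  # pragma: no cover - defensive
        raise TypeError(f"not a raster: {type(raster)!r}")
    return meta


def write_raster(raster, path) -> str:
    """Write a raster to a single-band TIFF; returns the path written.

    The inverse of the matching ``read_*`` function: grid values, nodata,
    pixel size and the CRS tag all roundtrip.
    """
    meta = _metadata_for(raster)
    grid = raster.grid
    if meta["kind"] == "factor":
        grid = np.asarray(grid, dtype="float32" if grid.dtype != np.float64 else "float64")
        nodata_ascii = "nan"
    else:
        grid = np.asarray(grid, dtype="int32")
        nodata_ascii = str(meta["nodata"])
    tifffile.imwrite(
        str(path),
        grid,
        description=json.dumps(meta),
        extratags=[(_GDAL_NODATA_TAG, "s", 0, nodata_ascii, True)],
    )
    return str(path)


def _read_band(path):
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        band = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, ValueError):
                meta = {}
    if band.ndim != 2:
        raise RasterFormatError(f"{path}: expected a single-band 2-D raster")
    return band, meta


def read_categorical(path, legend: Legend, pixel_size_m: float | None = None) -> CategoricalRaster:
    """Read an integer class-code raster, validating codes against *legend*.

    Unknown codes raise :class:`RasterValidationError` naming the offenders;
    a floating-point band raises :class:`RasterFormatError`.
    """
    band, meta = _read_band(path)
    if not np.issubdtype(band.dtype, np.integer):
        raise RasterFormatError(
            f"{path}: categorical raster band must be integer, got {band.dtype}"
        )
    px = pixel_size_m if pixel_size_m is not None else float(meta.get("pixel_size_m", 1.0))
    return CategoricalRaster(
        grid=band, pixel_size_m=px, legend=legend, crs_tag=str(meta.get("crs_tag", ""))
    )


def read_factor(path) -> FactorRaster:
    band, meta = _read_band(path)
    return FactorRaster(
        grid=np.asarray(band, dtype=float),
        pixel_size_m=float(meta.get("pixel_size_m", 1.0)),
        factor_name=str(meta.get("factor_name", "")),
        crs_tag=str(meta.get("crs_tag", "")),
    )


def read_rank(path) -> RankRaster:
    band, meta = _read_band(path)
    if not np.issubdtype(band.dtype, np.integer):
        raise RasterFormatError(f"{path}: rank raster band must be integer")
    return RankRaster(
        grid=band,
        pixel_size_m=float(meta.get("pixel_size_m", 1.0)),
        nodata_code=int(meta.get("nodata", 0)),
        crs_tag=str(meta.get("crs_tag", "")),
    )


def assert_aligned(a, b, tol_m: float = 1e-6) -> bool:
    """True iff two rasters share shape and pixel size (within *tol_m* metres)."""
    return a.shape == b.shape and abs(a.pixel_size_m - b.pixel_size_m) <= tol_m


def require_aligned(a, b, what: str = "rasters") -> None:
    if not assert_aligned(a, b):
        raise RasterValidationError(
            f"misaligned {what}: {a.shape}@{a.pixel_size_m} m vs {b.shape}@{b.pixel_size_m} m"
        )
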