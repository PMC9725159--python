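"""AHP weighting, factor ranking and Mangrove Health Index composition.

The scoring stage turns the four factor maps (canopy width, fragmentation,
density, diversity) into a single per-pixel health index:

1. factor weights come from an AHP pairwise comparison matrix on a 1–4
   preference scale, solved by Saaty's row geometric mean and normalised to
   sum 1 (expert membership-degree scoring against the core vector
   V = (4, 3, 2, 1) is supported as an alternative source);
2. each factor raster is cut into ranks 1..4 (worst → very good) by
   interval thresholds;
3. MHI = Σ_i w_i · rank_i per pixel, a value in [1, 4], then binned back
   into the four health classes.

Published reference weights for the four factors are (canopy 0.3,
fragmentation 0.4, density 0.2, diversity 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster_io import FactorRaster, RankRaster, require_aligned

__all__ = [
    "PairwiseMatrix",
    "WeightVector",
    "MembershipTable",
    "RankThresholds",
    "ahp_weights",
    "weights_from_membership",
    "rank_factor",
    "mhi_map",
    "classify_mhi",
    "DEFAULT_MHI_BINS",
    "default_thresholds",
    "thresholds_from_quantiles",
    "REFERENCE_WEIGHTS",
]

#: published factor weights: canopy, fragmentation, density, diversity
REFERENCE_WEIGHTS = (0.3, 0.4, 0.2, 0.1)

#: core score vector: rank r scores V[r-1]... listed very-good-first
CORE_VECTOR = (4.0, 3.0, 2.0, 1.0)

#: default equal-width MHI class bins over [1, 4]
DEFAULT_MHI_BINS = (1.0, 1.75, 2.5, 3.25, 4.0)


@dataclass
class PairwiseMatrix:
    """Reciprocal pairwise comparison matrix on a bounded preference scale."""

    m: np.ndarray
    factor_names: tuple[str, ...]
    scale_max: float = 4.0

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        n = self.m.shape[0]
        if self.m.ndim != 2 or self.m.shape != (n, n):
            raise ValueError(f"pairwise matrix must be square, got {self.m.shape}")
        if len(self.factor_names) != n:
            raise ValueError("factor_names length must match matrix size")
        if (self.m <= 0).any():
            raise ValueError("pairwise comparisons must be positive")
        if not np.allclose(np.diag(self.m), 1.0, atol=1e-9):
            raise ValueError("pairwise matrix diagonal must be 1")
        if not np.allclose(self.m * self.m.T, 1.0, atol=1e-9):
            raise ValueError("pairwise matrix must be reciprocal: m[j,i] = 1/m[i,j]")
        lo, hi = 1.0 / self.scale_max, self.scale_max
        if ((self.m < lo - 1e-9) | (self.m > hi + 1e-9)).any():
            raise ValueError(
                f"entries outside the 1-{self.scale_max:g} preference scale"
            )

    @classmethod
    def from_ratios(cls, weights, factor_names, scale_max: float = 4.0):
        """Perfectly consistent matrix m[i,j] = w_i / w_j from a positive
        ratio vector."""
        w = np.asarray(weights, dtype=float)
        return cls(m=w[:, None] / w[None, :], factor_names=tuple(factor_names),
                   scale_max=scale_max)


@dataclass
class WeightVector:
    """Non-negative factor weights summing to 1."""

    w: np.ndarray
    factor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if len(self.factor_names) != len(self.w):
            raise ValueError("factor_names length must match weights")
        if (self.w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(self.w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {self.w.sum()}")


@dataclass
class MembershipTable:
    """Expert membership degrees of each factor over the four ranks.

    Row i gives (r_i1..r_i4): the degree to which factor i belongs to each
    rank, summing to 1; the score vector V defaults to the core vector.
    """

    R: np.ndarray
    V: tuple[float, ...] = CORE_VECTOR
    factor_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2 or self.R.shape[1] != len(self.V):
            raise ValueError(f"membership table must be n×{len(self.V)}")
        if (self.R < 0).any():
            raise ValueError("membership degrees must be non-negative")
        if not np.allclose(self.R.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each membership row must sum to 1")


def ahp_weights(pm: PairwiseMatrix) -> WeightVector:
    """Saaty row-geometric-mean weights, normalised to sum 1.

    For a consistent matrix built from a ratio vector the vector is
    recovered exactly (up to floating point).
    """
    n = pm.m.shape[0]
    gm = np.exp(np.log(pm.m).sum(axis=1) / n)
    return WeightVector(w=gm / gm.sum(), factor_names=pm.factor_names)


def weights_from_membership(mt: MembershipTable) -> np.ndarray:
    """Score of each factor: Σ_j R_ij · V_j, bounded by [min V, max V].

    Normalise the returned scores to obtain weights."""
    return mt.R @ np.asarray(mt.V, dtype=float)


@dataclass
class RankThresholds:
    """Interval thresholds cutting a factor's values into ranks 1..4.

    ``intervals`` are ``(lo, hi, rank)`` triples, half-open ``[lo, hi)``
    except the interval with the greatest hi, which is closed at the top.
    Intervals must not overlap and must use each rank at most once.
    ``higher_is_better`` is descriptive metadata (the intervals already
    encode the direction).
    """

    factor_name: str
    intervals: tuple[tuple[float, float, int], ...]
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        ivals = sorted(self.intervals)
        if not ivals:
            raise ValueError("need at least one interval")
        ranks = [r for _, _, r in ivals]
        if len(set(ranks)) != len(ranks):
            raise ValueError(f"ranks reused across intervals: {ranks}")
        if any(r not in (1, 2, 3, 4) for r in ranks):
            raise ValueError(f"ranks must be in 1..4, got {ranks}")
        for (lo, hi, _) in ivals:
            if not lo < hi:
                raise ValueError(f"empty interval [{lo}, {hi})")
        for (_, hi_prev, _), (lo_next, _, _) in zip(ivals, ivals[1:]):
            if lo_next < hi_prev - 1e-12:
                raise ValueError("intervals overlap")
            if lo_next > hi_prev + 1e-12:
                raise ValueError("intervals leave a gap — must be exhaustive")
        self.intervals = tuple(ivals)

    @property
    def lo(self) -> float:
        return self.intervals[0][0]

    @property
    def hi(self) -> float:
        return self.intervals[-1][1]

    def rank_of(self, values: np.ndarray) -> np.ndarray:
        """Vectorised interval lookup; NaN → 0 (nodata); out-of-range
        values raise, naming the offender."""
        values = np.asarray(values, dtype=float)
        out = np.zeros(values.shape, dtype=np.int16)
        valid = ~np.isnan(values)
        oob = valid & ((values < self.lo) | (values > self.hi))
        if oob.any():
            bad = values[oob].ravel()[0]
            raise ValueError(
                f"{self.factor_name}: value {bad} outside threshold range "
                f"[{self.lo}, {self.hi}]"
            )
        for lo, hi, rank in self.intervals:
            top = hi == self.hi
            sel = valid & (values >= lo) & ((values <= hi) if top else (values < hi))
            out[sel] = rank
        return out


def default_thresholds() -> dict[str, RankThresholds]:
    """Default factor→rank calibrations.

    Fragmentation uses the windowed PLADJ percentage directly (80–100 → 4,
    65–80 → 3, 50–65 → 2, below 50 → 1).  Canopy cuts CONTIG at
    0.25/0.5/0.75.  Diversity ranks the count of distinct mangrove classes
    in the window (>2 → 4, 2 → 3, 1 → 2, none → 1).  Density has no
    scene-free default — build it with :func:`thresholds_from_quantiles`.
    """
    return {
        "fragmentation": RankThresholds(
            "fragmentation",
            ((80.0, 100.0, 4), (65.0, 80.0, 3), (50.0, 65.0, 2), (0.0, 50.0, 1)),
        ),
        "canopy_width": RankThresholds(
            "canopy_width",
            ((0.75, 1.0, 4), (0.5, 0.75, 3), (0.25, 0.5, 2), (0.0, 0.25, 1)),
        ),
        "species_richness": RankThresholds(
            "species_richness",
            ((2.5, 1e9, 4), (1.5, 2.5, 3), (0.5, 1.5, 2), (-0.5, 0.5, 1)),
        ),
    }


def thresholds_from_quantiles(
    factor: FactorRaster, quantiles=(0.25, 0.5, 0.75), higher_is_better: bool = True
) -> RankThresholds:
    """Scene-relative calibration: cut the factor's valid values at the
    given quantiles so the four classes hold roughly equal areas (used for
    density, whose field-unit classes have no fixed metric equivalent)."""
    values = factor.grid[factor.valid_mask]
    if values.size == 0:
        raise ValueError(f"{factor.factor_name}: no valid cells to calibrate on")
    qs = np.quantile(values, quantiles)
    lo = min(float(values.min()), qs[0]) - 1e-9
    hi = max(float(values.max()), qs[-1]) + 1e-9
    edges = [lo, *[float(q) for q in qs], hi]
    # guard against degenerate (tied) quantiles
    for i in range(1, len(edges)):
        if edges[i] <= edges[i - 1]:
            edges[i] = edges[i - 1] + 1e-9
    ranks = (1, 2, 3, 4) if higher_is_better else (4, 3, 2, 1)
    intervals = tuple(
        (edges[i], edges[i + 1], ranks[i]) for i in range(4)
    )
    return RankThresholds(factor.factor_name, intervals, higher_is_better)


def rank_factor(factor: FactorRaster, thresholds: RankThresholds) -> RankRaster:
    """Map each valid cell of a factor raster to its interval's rank;
    nodata propagates as 0."""
    return RankRaster(
        grid=thresholds.rank_of(factor.grid),
        pixel_size_m=factor.pixel_size_m,
        nodata_code=0,
        crs_tag=factor.crs_tag,
    )


def mhi_map(ranks: list[RankRaster], weights: WeightVector) -> FactorRaster:
    """Per-cell weighted sum of factor ranks: MHI = Σ_i w_i · rank_i.

    Bounded by [min rank, max rank] cell-wise for any simplex weights;
    nodata wherever any factor is nodata.
    """
    if len(ranks) != len(weights.w):
        raise ValueError("one rank raster per weight required")
    for other in ranks[1:]:
        require_aligned(ranks[0], other, "rank rasters")
    valid = np.ones(ranks[0].shape, dtype=bool)
    for rr in ranks:
        valid &= rr.valid_mask
    mhi = np.zeros(ranks[0].shape, dtype=float)
    for w, rr in zip(weights.w, ranks):
        mhi += w * rr.grid
    mhi[~valid] = np.nan
    return FactorRaster(
        grid=mhi,
        pixel_size_m=ranks[0].pixel_size_m,
        factor_name="MHI",
        crs_tag=ranks[0].crs_tag,
    )


def classify_mhi(mhi: FactorRaster, bins=DEFAULT_MHI_BINS) -> RankRaster:
    """Cut the continuous MHI surface into the four health classes
    (1 worst .. 4 very good).  Default bins are equal-width over [1, 4]."""
    bins = tuple(float(b) for b in bins)
    if len(bins) != 5:
        raise ValueError("bins must be 5 edges for 4 classes")
    thresholds = RankThresholds(
        "MHI",
        tuple((bins[i], bins[i + 1], i + 1) for i in range(4)),
    )
    return rank_factor(mhi, thresholds)
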