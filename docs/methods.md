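# Methods

## Scope and model

The package maps mangrove-forest health from categorical land-cover
rasters. Health is treated as a composition of four stand properties —
canopy width, fragmentation, density and plant diversity — each proxied by
a landscape metric computed in a 5×5-pixel moving window and returned to
the window's centre cell. The factor maps are cut into ranks 1–4 and
combined into the Mangrove Health Index, a per-pixel weighted sum of the
ranks. Upstream image classification is out of scope: the pipeline starts
from integer class-code grids with a legend marking which classes are
mangrove species.

Grid conventions: row-major with row 0 northernmost, 0-based `(row, col)`
indexing, areas as `cell_count × pixel_size_m²` (hectares = m²/10,000),
the CRS carried as an opaque tag. Patch connectivity is 4-connected and
adjacency counting is orthogonal-only throughout — diagonal neighbours
never join patches or contribute adjacencies.

## Metrics

* **CONTIG** (canopy width, per patch, range [0, 1]). Each pixel's
  contiguity value sums a 3×3 template over neighbours **in the same
  patch**; the patch value is `(mean − 1)/(v − 1)`. The template is the
  FRAGSTATS standard — centre 1, orthogonal 2, diagonal 1, so v = 13 —
  which puts single-pixel patches at exactly 0 and large compact patches
  near 1. The template is configurable in principle but no alternative is
  shipped; the standard weights are the only choice consistent with the
  printed range and the single-pixel anchor. Patch membership (not mere
  class identity) gates the template sum: with 4-connectivity a diagonal
  same-class cell can belong to a different patch and must not contribute.
* **PLADJ** (fragmentation, range [0, 100]). Like adjacencies as a
  percentage of all adjacencies for a class, using the double-count
  method: every orthogonal cell pair contributes once from each side.
  Pairs involving nodata are excluded. A class with zero adjacencies in
  scope has undefined PLADJ and is flagged as nodata rather than forced
  to a number.
* **PD** (density). `n/A × 10,000`: patches per hectare with A the valid
  area in m². The widely used FRAGSTATS convention adds another ×100
  (patches per 100 ha); that scale is exposed as an option
  (`per_100ha=True`) but the per-hectare form is the default.
* **SHEI** (diversity, range [0, 1]). Normalised Shannon entropy of class
  proportions. m counts the classes actually present; for m = 1 the
  normaliser ln m vanishes and the value is defined as 0 — a one-class
  landscape carries no evenness information, consistent with the lower
  bound. With a class subset (the mangrove species), proportions are
  taken among subset cells only, i.e. species evenness within mangrove.

Nodata cells are excluded from proportions, adjacencies and area unless a
caller passes an explicit extent area.

## Moving-window engine

The window value at a cell is, by construction, the whole-extent metric of
the `size × size` crop centred there; the test suite checks this
equivalence exhaustively against the whole-extent implementations on small
rasters. Design choices:

* Class-scoped metrics (CONTIG, PLADJ, PD) merge all mangrove codes into
  one super-class, because each factor map is a single health layer, not a
  per-species product. Per-class computation remains available by passing
  a single focal code.
* Patch structure is recomputed inside each window (patches clipped at the
  window boundary), so every centre cell receives a self-contained value.
* Window CONTIG is the area-weighted mean of per-patch CONTIG over the
  mangrove patches in the window — a window can hold several patches and
  one canopy value per cell is needed; area weighting matches the metric's
  per-cell averaging.
* Window PD uses `A = valid cells in window × pixel_size²`.
* Edge policy defaults to nodata (a half-window border is masked), which
  avoids biased shrunken windows; `shrink` is available. A minimum valid
  fraction (`nodata_policy`) can additionally mask windows dominated by
  nodata.
* Windows with no mangrove cells yield nodata for CONTIG and PLADJ
  (undefined), PD 0 is reported only when patches could exist, and SHEI
  over the mangrove subset is nodata when no mangrove is present.
* A fifth window statistic, species **richness** (count of distinct
  mangrove codes in the window), backs the diversity ranking rule (below).

The window is exhaustive and deterministic; no stochastic sampling of
window pixels is performed.

## Metric screening

Candidate factor maps are screened by pairwise Pearson correlation,
including a numeric encoding of the classification layer (CLS). No
canonical encoding of a categorical map for correlation exists, so the
package makes its choice explicit: mangrove cells keep their integer class
code, all other classes are 0, nodata stays nodata; the encoding is
configurable and recorded with the output. Cells nodata in either layer of
a pair are dropped pairwise, maximising usable cells per pair. Jointly
constant pairs have undefined r and are emitted as nodata entries; fewer
than 3 jointly valid cells is an error. R² of the simple linear fit equals
squared Pearson r and is provided directly.

## AHP weighting and ranking

Weights solve a reciprocal pairwise comparison matrix on a 1–4 preference
scale by Saaty's row geometric mean, `W̄_i = (Π_j m_ij)^{1/n}`, normalised
to sum 1. For any consistent matrix `m_ij = w_i/w_j` this recovers `w`
exactly; the reference weight vector (canopy 0.3, fragmentation 0.4,
density 0.2, diversity 0.1) is reproduced from its ratio matrix in the
acceptance checks. No consistency-ratio test is performed: weights here
come either from a consistent published vector or from explicit config.
An expert membership-degree table is supported as an alternative source:
factor score `Σ_j R_ij · V_j` against the core vector V = (4, 3, 2, 1),
normalised to weights. Precedence when several sources are configured:
explicit weights > pairwise matrix > membership table. This makes runs
deterministic when a config carries more than one device.

Rank thresholds map factor values onto ranks 1–4 through exhaustive,
non-overlapping intervals (half-open, top interval closed). The published
class definitions are in field units (crown diameter in metres, trees per
plot, species counts), while the factors are metric-valued; the
calibration between the two is not published, so the defaults are explicit
package choices, overridable in config and echoed into output metadata:

* fragmentation: windowed PLADJ % directly — 80–100 → 4, 65–80 → 3,
  50–65 → 2, below 50 → 1. The published class bounds for the two middle
  ranks overlap (65–79 vs 51–78); the implementation resolves the overlap
  minimally while keeping the "below 50 → worst" rule.
* canopy width: CONTIG at 0.25 / 0.5 / 0.75 (equal quarters of the
  metric's range).
* density: PD cut at scene quartiles (`thresholds_from_quantiles`), since
  tree-count classes have no fixed PD equivalent; the calibration is
  scene-relative and recorded per run.
* diversity: ranked on window species richness — more than 2 mangrove
  species → 4, exactly 2 → 3, 1 → 2, none → 1. SHEI is still computed and
  reported as the diversity factor map, but the published diversity
  classes are species counts, which richness expresses directly.

MHI is the weighted rank sum, bounded cell-wise by the minimum and maximum
factor rank for any simplex weights, monotone in every factor, and nodata
wherever any factor is nodata. The continuous surface is classified with
equal-width bins [1, 1.75), [1.75, 2.5), [2.5, 3.25), [3.25, 4] — four
output classes are required and no bin edges are published, so equal width
is the neutral default, configurable.

## Accuracy assessment

Rows are reference, columns predicted — the orientation under which every
per-class accuracy of the shipped Ca Mau validation counts reproduces its
printed value (e.g. PA of *R. apiculata* = 47/57 = 82%, UA = 47/50 = 94%).
Blank cells in the published table are read as zeros; only that reading
balances the row and column totals. Report rounding is nearest integer
percent, half up; unrounded values stay in machine output. One
inconsistency is documented rather than reconciled: the overall accuracy
stated alongside the published counts is 80%, but the counts themselves
yield trace/total = 169/222 ≈ 76.1%; the package always reports the value
the matrix yields.

## Change analysis

Class areas are tabulated per date; transitions are counted over jointly
valid cells and reported in cells and hectares. Health change compares the
two dates' classified MHI maps (post-classification comparison): improved
where the class rose, degraded where it fell, stable otherwise; the raw
class difference is kept as a diagnostic layer. Cells nodata at either
date are excluded, so no transitions are fabricated at mask edges.

## Synthetic data

The generator provides the statistical structure the analysis assumes,
not imagery realism:

* **Landscapes** are neutral-landscape models: a standard-normal field,
  Gaussian-smoothed with σ = 4·clumping pixels (clumping ∈ [0, 1]; 0 means
  no smoothing, i.e. an i.i.d. field), cut at the quantiles of the
  requested class proportions. Proportions are therefore near-exact, and
  smoothing raises spatial autocorrelation, hence PLADJ, monotonically in
  expectation — verified over 20 seeds on a {0, 0.5, 1} clumping grid.
  Default scene: 100×100 cells at 1.5 m, five classes (four mangrove, one
  non-mangrove matrix) with mangrove covering ~70%, clumping 0.6 —
  a dense, aggregated forest with embedded ponds.
* **Series** iterate two mechanisms per step: *expansion* converts
  non-mangrove cells on the mangrove frontier (orthogonally adjacent to
  mangrove) to the code of a neighbouring mangrove cell, emulating
  seaward accretion planting; the expansion rate is the fraction of the
  non-mangrove pool converted per step, capped by the frontier size.
  *Fragmentation* punches out mangrove interior cells (all 4 orthogonal
  neighbours same class), reassigning them to the first non-mangrove
  code, emulating shrimp-pond conversion inside the forest; its rate is
  the fraction of interior cells removed per step. Expansion-only series
  therefore have strictly non-decreasing mangrove area and zero
  mangrove-loss transitions; positive fragmentation strictly removes like
  adjacencies and drives class PLADJ down across dates.
* **Confusion sampling** expands any non-negative count matrix into the
  exact multiset of (reference, predicted) pairs; re-tabulation is the
  identity, which is how the shipped validation counts are exercised end
  to end.

What the generator does **not** emulate: spectral texture, sensor effects,
georeferencing, tidal flats, or rates calibrated to real accretion
figures. Passing tests demonstrate correctness of the metric and scoring
machinery on landscapes with controllable aggregation — they do not
validate ecological conclusions about any real site.

## Numerical choices and problem sizes

All generators take explicit integer seeds (numpy `default_rng`);
identical seed and spec give bit-identical rasters, and the pipeline
itself is deterministic, so reruns produce byte-identical outputs
(checksummed in the run manifest). Alignment checks compare shapes exactly
and pixel sizes within 1e-6 m. Weight and membership validation uses 1e-9
tolerances. Quantile-based thresholds pad degenerate (tied) edges by 1e-9
to keep intervals non-empty.

Test and acceptance problem sizes are chosen so the exhaustive oracles
stay exact: brute-force metric comparisons run on 200 random rasters up to
20×20; window/crop equivalence on 12×12 rasters with 5×5 windows;
stochastic generator properties on 60×60–80×80 scenes over 20 seeds; the
acceptance pipeline on an 80×80, three-date series with expansion 0.08 and
fragmentation 0.03 per step — large enough for stable trajectories, small
enough to recompute everything from scratch in seconds.

## Known limitations

* The factor→rank calibrations other than fragmentation are package
  defaults, not published values; conclusions are sensitive to them and
  they should be set from field knowledge per study area.
* Window PD on a 5×5 window is coarse (25 cells); its scene-relative
  quartile ranking is stable, but absolute per-hectare densities from tiny
  windows should not be compared across scenes with different pixel sizes.
* No AHP consistency ratio is computed; inconsistent expert matrices are
  accepted as long as they are reciprocal and within scale.
* No reprojection or resampling: all rasters of a run must already share
  grid and pixel size.
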