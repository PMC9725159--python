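# mangrove-health

Quantitative mangrove-forest health mapping from classified satellite
imagery, built for coastal-forest monitoring programmes (the motivating
system is the Mui Ca Mau mangrove, Ca Mau province, Vietnam — *Rhizophora
apiculata*, *Avicennia alba* and their mixed stands, under pressure from
shrimp-pond conversion).

The package takes categorical land-cover rasters (one per date), computes
four moving-window landscape metrics as health factors, weights them by
the Analytic Hierarchy Process (AHP), composes a per-pixel **Mangrove
Health Index (MHI)**, assesses classification accuracy, and quantifies
change between dates.

## The model

Four factors characterise stand condition, each measured by a landscape
metric inside a 5×5-pixel moving window whose value is returned to the
centre cell (orthogonal adjacencies only; diagonals are ignored):

| Factor | Metric | Definition |
| --- | --- | --- |
| canopy width | CONTIG | `((Σ_r c_ijr / a_ij) − 1) / (v − 1)`, 3×3 template (centre 1, orthogonal 2, diagonal 1; v = 13), range [0, 1] |
| fragmentation | PLADJ | `100 · g_ii / Σ_k g_ik`, double-count like adjacencies, range [0, 100] |
| density | PD | `n / A × 10,000` patches per hectare (A in m²) |
| plant diversity | SHEI | `−Σ P_i ln P_i / ln m`, range [0, 1] |

Patches are 4-connected. Class-scoped factors treat all mangrove classes
as one super-class; SHEI keeps the species classes apart.

Each factor raster is cut into ranks 1–4 (worst → very good), and

```
MHI = Σ_i W_i · V_i ,   MHI ∈ [1, 4]
```

with weights `W` from Saaty's row-geometric-mean solution of a reciprocal
pairwise comparison matrix on a 1–4 preference scale (reference weights:
canopy 0.3, fragmentation 0.4, density 0.2, diversity 0.1) and `V_i` the
per-pixel factor rank. The MHI surface is binned back into four health
classes; two dates' class maps give an improved/stable/degraded change
map, and class transition matrices quantify land-cover conversion in
hectares.

Accuracy assessment follows the standard confusion-matrix scheme
(rows = reference, columns = predicted): per-class producer and user
accuracy and overall accuracy.

Because no imagery is distributed, the `synthetic_data` module generates
neutral-landscape test inputs: clumped multi-class maps (smoothed Gaussian
field cut at proportion quantiles), multi-date expansion/fragmentation
series, and labeled sample sets realising any given confusion matrix.

## Worked example

```python
import numpy as np
from mangrove_health import (
    LandscapeSpec, SeriesSpec, generate_series, factor_stack,
    rank_factor, mhi_map, classify_mhi, mhi_change,
    PairwiseMatrix, ahp_weights,
)
from mangrove_health.health_scoring import default_thresholds, thresholds_from_quantiles
from mangrove_health.window_engine import WindowSpec, windowed_metric

# three dates of a clumped five-class landscape: mangrove expands seaward
# while ponds are punched into the forest interior
series = generate_series(SeriesSpec(
    base=LandscapeSpec(n_rows=80, n_cols=80, clumping=0.7, seed=1),
    n_dates=3, expansion_rate=0.08, fragmentation_rate=0.03, seed=1,
))

weights = ahp_weights(PairwiseMatrix.from_ratios(
    (0.3, 0.4, 0.2, 0.1),
    ("canopy_width", "fragmentation", "density", "diversity"),
))
print("AHP weights:", dict(zip(weights.factor_names, weights.w.round(3).tolist())))

thresholds = default_thresholds()
classified = []
for i, raster in enumerate(series):
    canopy, frag, dens, _ = factor_stack(raster)
    richness = windowed_metric(raster, WindowSpec(
        metric="RICHNESS", focal_classes=raster.legend.mangrove_codes))
    ranks = [
        rank_factor(canopy, thresholds["canopy_width"]),
        rank_factor(frag, thresholds["fragmentation"]),
        rank_factor(dens, thresholds_from_quantiles(dens)),
        rank_factor(richness, thresholds["species_richness"]),
    ]
    mhi = mhi_map(ranks, weights)
    classified.append(classify_mhi(mhi))
    print(f"date {i}: mean MHI = {np.nanmean(mhi.grid):.3f}")

change = mhi_change(classified[0], classified[-1])
print("health change date 0 -> 2:", change.counts())
```

Output:

```
AHP weights: {'canopy_width': 0.3, 'fragmentation': 0.4, 'density': 0.2, 'diversity': 0.1}
date 0: mean MHI = 3.024
date 1: mean MHI = 3.016
date 2: mean MHI = 3.013
health change date 0 -> 2: {'improved': 356, 'stable': 4914, 'degraded': 59}
```

The consistent ratio matrix recovers the reference weights exactly. Mean
MHI drifts down slightly over the series: interior fragmentation lowers
window PLADJ (the heaviest-weighted factor) faster than frontier
expansion raises canopy contiguity. Cell-wise, frontier accretion improves
356 cells while pond punch-outs degrade 59.

The same flow is scriptable from the shell — `mangrove-health simulate`,
`factors`, `correlate`, `ahp`, `mhi`, `accuracy`, `change`, or `run` with
a single YAML config (legend, dated raster paths, window size, weights
source, thresholds, MHI bins).

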