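# Methods

`aumex` maps *potential environmental exposure* to abandoned uranium mines
(AUMs) with a fuzzy GIS multi-criteria decision analysis (GIS-MCDA), and uses
that model as a test bed for a question about input data quality: how does the
choice of wind data source — sparse direct measurements versus a dense but
interpolated gridded reanalysis product — change the accuracy of the final
exposure surface? Because the real inputs (mine inventories, station records,
reanalysis grids, stream-sediment geochemistry) cannot be redistributed, the
package generates a synthetic study area with the statistical structure the
analysis assumes, and runs the complete experiment end to end against known
ground truth.

## The exposure model

Eight criteria rasters are computed on a shared planar grid (row-major,
origin at the top-left corner, y decreasing southward; coordinates in metres,
no geodesy — the analysis is projected):

1. **AUM proximity** — Σⱼ areaⱼ/dᵢⱼ over mines within 50 km, distances floored
   at half a cell so source cells stay finite.
2. **Downslope drainage** — each mine's downstream flow path is traced on the
   DEM by D8 steepest descent; a drainage zone whose centroid lies within a
   snap threshold of a path contributes 1/(along-path distance in km) per
   source; off-path zones are 0. Zones are a Voronoi partition of random
   seeds, standing in for hydrologic response units; the default snap
   threshold is the mean zone boundary length, mirroring the original
   mean-shape-length rule.
3. **Wind index** — the bespoke downwind-susceptibility statistic. With θ the
   bearing from a receptor cell toward source j, β the cell's prevailing
   blowing-from direction, D the distance in km (half-cell floor) and
   Sv ∈ (0,1] the max-normalized speed:

       f = (1 − cos(180° + (θ − β))) / 2          directional factor ∈ [0,1]
       Wi = sqrt( Σⱼ (f/D)·Sv )   over terms with f > 0.5 (strict)

   f peaks at 1 for receptors directly downwind (θ = β) and vanishes directly
   upwind; the strict cutoff keeps only sources within the ±90° downwind
   wedge, with a 1e−9 guard so exact-crosswind cells (f = 0.5 up to rounding)
   stay excluded. The printed form of this equation is ambiguous in two
   places; we threshold the dimensionless factor alone (a distance-inclusive
   threshold would be unit-dependent) and an opposite phase convention is
   config-selectable (`downwind_peak=False`).
4. **Topographic wind exposure** — the surface-illumination form with the
   wind in place of the sun: cos α = cos μ sin β_w + sin μ cos β_w cos(δ−γ),
   multiplied by Sv. μ is slope and γ aspect from the Horn 8-neighbour
   stencil (aspect undefined on flat cells, where sin μ = 0 makes the term
   vanish); δ the blowing-from direction; β_w the wind's inclination above
   the horizontal, default 0 (horizontal wind), giving sin μ cos(δ−γ) Sv.
5. **Landforms** — six classes from the topographic position index (TPI,
   elevation minus the circular-neighbourhood mean, centre excluded, edges
   truncated) with the standard slope-augmented single-scale scheme: with s
   the TPI standard deviation, valley ≤ −s, lower slope ≤ −s/2, flat
   (|TPI| < s/2, slope ≤ 5°), mid-slope (slope > 5°), upper slope < s,
   ridge ≥ s.
6. **Road proximity** — Euclidean distance to the nearest road segment.
7. **Groundwater hazard** — inverse-distance-weighted (power 2) interpolation
   of well hazard indices; exact at wells.
8. **NDVI** — a vegetation index passthrough.

Each layer is standardized to a [0,1] membership by one of the four classic
fuzzy families. Large: 1/(1+(x/m)^−s); Small: 1/(1+(x/m)^s); the MS variants
derive their transition from the layer mean and standard deviation
(MSLarge = 0 below a·mean, then 1 − b·sd/(x − a·mean + b·sd); MSSmall its
complement). Defaults: midpoint = layer median of positive values, spread 5,
a = b = 1; non-positive inputs take the limiting membership (0 for Large, 1
for Small), which makes zero-valued drainage cells well defined. The ordinal
landform code 1–6 enters Small, so valleys — deposition zones — get the
highest membership. Default assignment: MSLarge for proximity and
topographic exposure, Large for wind index and groundwater hazard, Small for
drainage value, landforms and NDVI, MSSmall for road distance.

Criterion weights come from a random-forest regression (500 trees, unlimited
depth, impurity importances, fixed seed; all config-exposed) of observed
concentration on the eight fuzzified layers sampled at 750 training
locations; importances are normalized to sum to one. The exposure surface is
the weighted linear combination Σ w_k·layer_k ∈ [0,1], one surface per MET
combination since layers 3–4 differ between combinations.

## MET data reduction and fusion

Station records reduce to the centre of the modal 22.5° wind-rose sector
(16 sectors centred on north; ties to the lowest sector) and the arithmetic
mean speed. Sources fuse under a replacement rule: for each direct station
the four nearest gridded points are removed (as a set union, so a point
shared between stations is removed once), then surviving gridded points and
all direct points are unioned. Wind is rasterized by nearest-point
assignment (Euclidean, ties to the lowest point id), and speed is scaled by
the domain maximum into (0,1].

## Geographically weighted regression

Validation fits a single-predictor GWR of observed concentration on modeled
exposure at sample locations: local weighted least squares with an adaptive
bisquare kernel whose bandwidth (neighbour count) minimizes the corrected
AIC via golden-section search. The accuracy statistic is the global
R² = 1 − RSS/TSS of the locally fitted values. The implementation is
vectorized (all n local 2×2 normal systems solved at once from the n×n
kernel matrix), which keeps hundreds of repeated fits tractable; locally
singular systems (locally constant predictor) fall back to the local
weighted mean; a globally constant predictor is rejected as a degenerate
fit. In repeated-subset validation the bandwidth is selected on the first
subset and held fixed across repetitions, so the repetitions measure
sampling variability of the fit rather than of the bandwidth search.

## The synthetic world

All generators are pure functions of (parameters, seed). Defaults describe a
64 × 64 km domain at 128 × 128 cells of 500 m — the real ~70,000 km² study
area scaled to desk size (factor ≈ ¼), with radii scaled accordingly.

- **Terrain**: spectral synthesis of fractional Brownian noise, amplitude
  ∝ k^−(1+roughness), rescaled to [0, relief] (defaults 1.3, 600 m).
- **Mines**: Poisson-cluster pattern, 5 clusters × 12 mines, offspring
  scatter 3 km, areas log-uniform in [2·10³, 2·10⁵] m².
- **Truth wind**: standardized Gaussian random fields with 20 km correlation
  length; direction = 225° (southwest) ± 25° field, wrapped; speed
  4 ± 1.2 m/s, clipped at 0. Standardization makes the domain circular mean
  equal the prevailing direction by construction.
- **MET sources**: the *direct* arm samples the truth exactly at 18 stations
  — 5 anchored at the mine-cluster centres (remediation-program stations are
  sited at the contaminated sites themselves) and 13 placed by jittered
  stratified sampling (an airport network sited for coverage). The *gridded*
  arm smooths the truth over 10 km, adds a systematic +15° direction bias,
  and samples on a regular 8 km lattice (the 32 km reanalysis spacing at ¼
  scale). The degradation is the only difference between the two arms.
- **Ancillary**: 150 wells with lognormal (right-skewed) hazard indices, 6
  random road polylines, NDVI as a smooth field squashed into [−1, 1] by
  tanh, 300 Voronoi drainage zones.
- **Validation samples**: 4000 locations uniform over the grid with
  concentration exp(1 + 3·E + ε), ε ~ N(0, 0.1), where E is the
  weighted linear combination of the *fuzzified truth* criteria (truth wind,
  known weights). The log-linear link is the simplest monotone choice that
  produces the right-skewed marginal that stream-sediment uranium
  concentrations show; the noise level and link coefficients are config
  parameters, not claims about the real survey.
- **True weights** (0.22, 0.02, 0.28, 0.06, 0.04, 0.09, 0.16, 0.13): strictly
  distinct so that rank-based weight recovery is well posed, with the wind
  index carrying the largest share, consistent with the aeolian-transport
  focus of the model.

What the generator does *not* emulate: real orographic wind–terrain
coupling (wind and terrain are independent fields), temporal structure
(records are already reduced to mode/mean), spatially correlated sampling
noise, the irregular spatial coverage of the historical geochemical survey,
and land-cover/soil heterogeneity (drainage zones are geometric, not
hydrologic). Passing tests therefore demonstrate that the pipeline's
machinery is correct and that its comparative conclusions hold under the
stated statistical assumptions — not that the real-world R² magnitudes
would be reproduced.

## The comparison experiment

`aumex.experiment.met_comparison_experiment` runs independent replicate
worlds at half resolution (64 × 64 cells at 1 km, 1500 samples); within a
world both arms share every input except the MET source, RF weights are
refit per arm from the same training rows, and the repeated-subset GWR
validation (99 subsets of 1000) uses identical subsets for both arms. The
reported result is each arm's mean R² per world and the fraction of worlds
the combined-direct arm wins. Design notes from the calibration of this
experiment: the margin between arms is small (order 0.003 in R²) because
GWR's local fitting absorbs smooth distortions such as a constant direction
bias, so the experiment needs large validation subsets and the anchored
station placement to resolve the ordering consistently; with the default
settings the direct arm wins in ≥ 90% of replicate worlds, with the margin
concentrated near zero in the worlds it loses.

## Numerical choices and degenerate inputs

- Distances in all reciprocal-distance layers floored at half a cell size.
- Wind-index cutoff strict, with a 1e−9 tolerance at the f = 0.5 boundary.
- Flat cells: aspect NaN; topographic exposure 0 when β_w = 0; zero-variance
  TPI degenerates to the flat/mid split by slope.
- ANOVA sampling uses identical cell locations across surfaces; zero cells
  are offset by the smallest positive sampled value before log2; identical
  groups report F = 0.
- All CSV artifacts are written with `%.17g` and read with round-trip float
  parsing, so staged CLI runs are byte-identical to the in-memory pipeline.
- Sub-seeds for each stochastic stage are derived from the master seed via
  `numpy.random.SeedSequence`, all below 2³¹.

## Problem sizes

The default run uses the 128 × 128 grid with 99 repeated validation subsets
of 1000 (scaled down from 999 × 3500 on the real data), k-fold CV with
train 750 / test 350, ANOVA on 500 cells, and a 33-site scale test over the
seven radii 25–175 km; the replicate-world experiment uses 20 worlds at
64 × 64. These sizes were chosen so the full analysis runs comfortably on a
single CPU while leaving every statistic's sampling error well below the
effects being measured.

## Known limitations

- RF impurity importances are a biased estimator of contribution under
  correlated criteria (proximity-type layers correlate through the shared
  mine geometry); weight recovery is assessed by rank correlation, not by
  absolute agreement.
- GWR's global R² rewards smooth predictors; surfaces with localized
  artifacts (nearest-station mosaics) score slightly worse than equally
  faithful smooth surfaces, which compresses the measured advantage of
  direct MET data relative to its fidelity advantage.
- The six-class landform thresholds and the fuzzy parameter defaults are
  field-standard conventions, not fitted values.
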