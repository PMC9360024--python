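# Methods

## Exposure model

All analysis happens on aligned square-cell rasters in a projected metric
coordinate system (the buffer arithmetic needs meters; geographic-CRS
rasters are rejected at read time rather than silently mis-measured).
Greenspace enters as a fractional cover grid in [0, 1]; a binary
finer-resolution map can be block-averaged onto the population grid with
`aggregate_fraction` (dimensions must divide evenly — no implicit padding or
resampling anywhere in the package; alignment mismatches are errors).

For a zone with cells i = 1..N:

- physical coverage `GC = (1/N) Σ G_i`;
- buffered exposure of a cell, `G_i^d` = mean of the greenspace fraction
  over all cells whose center lies within Euclidean distance d of cell i's
  center;
- population-weighted exposure `GE^d = Σ P_i G_i^d / Σ P_i`.

Kernel membership uses cell-center distance with an *inclusive* boundary
(≤ d, with a 1e−12 relative tolerance so cells at exactly d are kept); the
center cell always belongs, so radii below the cell size make the focal
mean an identity. At raster edges and around nodata cells the kernel is
renormalized over the cells actually present — constants are exact fixed
points and city fringes are not artificially darkened. `G^d` is computed
over the full raster *before* zonal masking: greenspace just outside an
administrative boundary is physically present in residents' neighborhoods
and therefore counts. Cells with zero population contribute nothing to
`GE^d` but remain in `GC`. Fractions are carried in [0, 1] internally;
percentages appear only in reports. Zones with no valid cells or zero
population are reported with an error flag, never silently dropped.

Buffer sensitivity between radii d1 and d2 is the mean over zones of
`|GE^d1 − GE^d2|`, reported in percentage points.

## Inequality

Exposure inequality of a zone is the population-weighted Gini of the
per-cell pairs `(G_i^d, P_i)` at the primary radius. The Lorenz curve sorts
cells ascending by exposure (ties kept in cell-index order — the Gini is
tie-order invariant, the stored curve just needs a convention) and
accumulates shares of population (x) and of population×exposure (y); the
Gini is one minus twice the trapezoidal area under the cell-level curve.
No percentile binning is applied: at cell resolution the trapezoidal value
agrees with the O(n²) pairwise formula `Σ w_i w_j |v_i − v_j| / (2 W² μ)`
to floating precision, which the tests exploit as an independent oracle.

A zone whose weighted exposure is identically zero has an undefined Lorenz
normalization; it is returned as Gini 0 with a `degenerate` flag (rather
than an error) so batch runs complete, and flagged zones are excluded from
downstream driver analysis. Zones need at least two positively weighted
cells. Category bands are half-open with defaults t_low = 0.3,
t_high = 0.5 (configurable): `low` below 0.3, `medium` in [0.3, 0.5),
`high` at and above 0.5. These bracket the range between well-provisioned
city collections (mean Gini ≈ 0.2–0.27) and highly unequal ones (≈ 0.47).

## Seasons

Month-to-season labeling is hemispheric: in the north, spring is
March–May, summer June–August, autumn September–November, winter
December–February; the south is shifted by two quarters. A seasonal stack
may be keyed directly by local season (the synthetic generator's output) or
by calendar quarter (DJF/MAM/JJA/SON), in which case each zone's
`hemisphere` attribute ("N"/"S") resolves quarters to local seasons; zones
without the attribute are flagged. Zones straddling the equator must
declare one hemisphere.

Per season the pipeline recomputes `GE^d`, the Gini, and the coefficient of
spatial variation `csv = σ/μ` of the zone's gridded exposure field `G^d`
(spatial variation of supply around residents, *unweighted* by population).
`cstv` is the standard deviation of the four seasonal csv values. Both σ
and the cstv std are *population* (ddof = 0) standard deviations: the four
seasons are the complete population of seasons, not a sample. Both
statistics are invariant to uniform rescaling of exposure. The
summer–winter Gini difference `dGini_sw` and the csv difference `dcsv_sw`
are both emitted; the property tests regress `|dGini_sw|` on `cstv`, which
is the relation the package treats as primary.

## Landscape metrics

Patches are connected components of a binary greenspace map, default
8-connectivity (corner-adjacent cells connect; 4-connectivity available).
Per-patch area is cell count × cell area; perimeter is the exposed
cell-edge length, counting edges shared with background, nodata, *and the
raster/zone boundary* — the convention that keeps perimeter conserved when
a patch is clipped, and the one the brute-force edge-count oracle in the
tests implements. Summary metrics: coverage rate (foreground/zone area),
mean and largest patch size in m² (plus `lpi`, the largest patch as a
fraction of zone area, since "largest patch" is reported both ways in the
landscape literature), mean per-patch perimeter–area ratio (m/m²), mean
shape index `0.25·perimeter/√area` (1 for solid squares, larger for
complex shapes), and edge density in m/ha. Binarization threshold defaults
to 0.5 on fractional maps; metric tests use explicitly binary inputs.

## Drivers

Covariates are min–max rescaled to [0, 1]; the Gini response stays raw.
Constant columns are flagged, mapped to 0, and excluded from screening.
Screening keeps a covariate when its Pearson correlation with the response
has p < 0.001 and |r| > 0.1 and the partial correlation controlling for
all other candidates has |r| > 0.1; p-values are two-sided and uncorrected
for the 16 tests (fixed thresholds, not FDR control, are the screening
rule). Partial correlations are computed by `pingouin.partial_corr`; the
tests independently verify them against the residual-regression definition.
Screening below 20 rows is refused as unstable.

The four nested OLS models are geography ({lat}), climate ({prcp, vpd}),
landscape ({gcr, ed}), and the full five-covariate model. Because the
standardization behind published coefficient tables is often ambiguous, the
package reports both the raw-scale coefficients (response per unit of the
0–1 covariate) and standardized (z-score) coefficients, with standard
errors, two-sided p-values, and adjusted
`R²_adj = 1 − (1 − R²)(n − 1)/(n − p − 1)`. Rank-deficient designs raise an
error naming the collinear set. VIFs are `1/(1 − R²_j)` from per-covariate
auxiliary regressions, with an infinity flag under perfect collinearity.

Variance partitioning follows the two-set commonality-analysis convention
of R's `vegan::varpart`, on adjusted R² by default (raw-R² mode available):
with `R²_a`, `R²_b`, `R²_ab` from fits on provision ({gcr}),
configuration ({ed}), and both, the unique fractions are
`R²_ab − R²_b` and `R²_ab − R²_a`, the joint fraction
`R²_a + R²_b − R²_ab`, and the residual `1 − R²_ab`; the four sum to 1 by
construction. Joint fractions can legitimately be negative (suppression)
and are reported as-is with a warning rather than truncated.

## Synthetic landscapes

The generators reproduce the *statistical* structure the analysis cares
about, not city morphology:

- `gen_gaussian_field` smooths white noise with a Gaussian kernel of scale
  `correlation_length` (meters; wrapped boundaries for stationarity) and
  standardizes to exactly zero mean, unit variance.
- `gen_greenspace` maps the field through the normal CDF (rank-preserving
  uniform scores) and a monotone power transform `u^θ`, with θ solved by a
  1-D root find so the realized mean equals `target_coverage` to floating
  precision — well inside the stated 1/(2·n_cells) tolerance.
- `gen_population` exponentiates `pop_clustering` × a standardized mixture
  of the (standardized) greenspace field and an independent field, mixed
  with weight `pop_green_corr`, so the population–greenspace correlation
  carries the requested sign; counts are integerized by largest remainder
  (ties by cell index), making the total *exactly* `pop_total`.
  `pop_green_corr` is a free experimental knob, not an estimate of any
  real joint distribution.
- `gen_seasonal_stack` marks a seeded `deciduous_fraction` subset of green
  cells and scales them by `winter_retention` in winter and
  `shoulder_retention` in spring/autumn; summer is the untouched baseline
  and evergreen cells never change.
- `gen_city_collection` draws 16 covariates i.i.d. normal per city and
  builds the Gini response as intercept (default 0.35) + planted linear
  effects on the rescaled covariates + Gaussian noise, clipped to [0, 1];
  clipping is counted and logged, and recovery tests run in regimes where
  it is rare (≲ 0.1% of rows).

Defaults: 100 m cells, 500 m correlation length, coverage 0.35, and the
500/1000/1500 m radius set with 500 m primary. What passing tests on these
landscapes demonstrate is that the *estimators* are correct (oracle
equivalence, conservation, planted-parameter recovery, direction of the
coverage-vs-exposure gap, the positive Gini-swing/cstv relation); they do
not demonstrate anything about real cities' street-level morphology,
demographic strata, or mobility, which the generators deliberately omit.

## Numerical choices and problem sizes

Rasterization assigns each cell to the zone containing its center
(boundary centers count as inside; overlaps resolve to the first zone in
list order with a warning). GeoTIFF round-trips are float32. The Gini is
clipped of sub-1e−15 floating dust at the equality end. Test and
acceptance problem sizes — 48–256-cell grids, 25–100 zones, 1000-city
driver tables, 1000 Gini oracle instances — were chosen so the full suite
exercises every code path at statistically meaningful sample sizes while
completing in seconds.

## Known limitations

No reprojection, resampling, or mosaicking; non-square cells are rejected.
No travel-time/network accessibility, no greenspace-size thresholds (all
greenspace counts, deliberately), no demographic subgroup decomposition,
no decomposable inequality indices (Theil, Atkinson), and no
spatial-autocorrelation-adjusted regression in the driver models. Seasonal
spring and autumn share one retention parameter, so the synthetic shoulder
seasons are identical by construction.
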