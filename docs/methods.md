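# Methods

This note documents the models and procedures implemented in
`ecburden`, the parameters that matter, the numerical choices made
where the design was genuinely open, and the limits of what the
synthetic verification shows.

## The analysis chain

The pipeline estimates the mortality burden of long-term elemental
carbon (EC) exposure in two stages on a shared regular planar grid
(square cells, 10 km by default; planar km coordinates throughout —
map projection is delegated to whoever produces the native fields, and
a projection hook belongs in the reader layer, not the core).

**Stage 1, exposure.** Thirteen predictors — road length, population
density, reanalysis black-carbon concentration, EC emissions, total and
absorption aerosol optical depths (two absorbing bands), NDVI, cloud
fraction, wind direction, wind speed, boundary-layer height, visibility
— arrive on their own native lattices and temporal resolutions (static,
monthly, daily). Gridded products are brought onto the analysis grid by
exact area-weighted averaging; station-like data (visibility) by
inverse-distance weighting. A random-forest regressor is trained on
site-day rows joining monitor EC observations to the regridded
predictors at the monitor's cell, evaluated out-of-bag, and then
applied to every cell-day with complete predictors.

**Stage 2, burden.** Daily predictions are averaged to cell-year annual
means, population-weighted to regional/national series, and fed through
the comparative-risk chain RR = exp(β(x − x_cf)), PAF = (RR − 1)/RR,
AD = PAF·POP·I, computed per cell-year and summed exactly to region,
nation and period-cumulative totals. Uncertainty is propagated by
re-running the chain at the lower and upper confidence bounds of β;
exposure-model uncertainty is deliberately out of scope.

## Regridding

*Areal averaging* factorises into one-dimensional interval-overlap
matrices for rectilinear lattices, so each target cell is the exact
overlap-area-weighted mean of the valid source cells it intersects.
Cells with zero valid overlapping area are masked, never filled.
Averaging a field linear in the coordinates reproduces it exactly at
cell centroids; constants are preserved.

*IDW* uses weights d^(−p) over the k nearest points, defaults p = 2 and
k = 8 (conventional choices; the method's power and neighbourhood are
analyst decisions and both are configuration, not constants). A query
within 1e-9 × cell size of a data point returns that point's value
exactly; outputs are convex combinations and therefore bounded by the
data range. Whether IDW should use all stations or a neighbourhood is
genuinely open; the neighbourhood is configurable and recorded in the
run manifest.

Assignment of operators to variables (gridded products averaged,
visibility interpolated) is itself configuration so a run is auditable.

## Exposure model

`ExposureRandomForest` wraps a bagged ensemble of regression trees
(scikit-learn) behind a fit/predict estimator interface. Defaults:
500 trees, p/3 features per split, unlimited depth, leaf size 1,
seeded; all exposed as parameters. Out-of-bag evaluation scores each
observation only with trees whose bootstrap sample excluded it; a
bag-membership hook (`inbag_counts`) makes this auditable.

Two R² conventions are computed and logged: the squared Pearson
correlation of OOB predictions vs observations (the headline metric,
matching the usual observed-vs-predicted regression presentation) and
the 1 − SSE/SST variant. Monthly evaluation aggregates site-months
with at least eight daily observations — the strict reading of "more
than seven"; the threshold is configuration.

Permutation importance reports, per predictor, the mean increase in
RMSE and decrease in R² when that column is shuffled while the others
are unchanged, averaged over repeats, plus a share normalised over
positive error increases. Rows with any missing predictor are dropped
and counted, not imputed. Masked cells (e.g. under a synthetic
satellite swath gap) are flagged missing in the prediction surface,
never zero-filled, and no gap-filling is attempted.

## Aggregation

Annual means use only unmasked days; a cell-year with fewer than 60
valid days (configurable) is masked. Seasons are MAM/JJA/SON/DJF with
December attached to the following year's winter; the final study
year's December is dropped from period-average winter means (its winter
is truncated) and logged. Population-weighted means are
Σ pop·x / Σ pop over unmasked member cells; the national mean is
exactly the population-weighted mean of regional means weighted by
regional population totals. Regional trends are OLS of the annual
series on year; percent change over the period is taken from the
fitted line's endpoint values (raw first/last is also reported),
because single-figure change summaries should not depend on the noise
of two individual years.

## Burden

β defaults to 0.06 per µg m⁻³ (95% CI 0.05–0.07), a pooled cohort
log-RR slope for long-term EC and all-cause non-accidental mortality.
The exposure increment β refers to is an explicit configuration field
(`per_ugm3`), never hard-coded, because published slopes are quoted per
varying increments. Toxicity is assumed constant over the period.

The counterfactual x_cf defaults to the single lowest cell-year
annual-mean EC of the period applied everywhere (a global floor in the
GBD tradition, conservative and comparable across regions); per-cell
minima and fixed values are alternative modes. By construction of the
min-based modes x ≥ x_cf, hence RR ≥ 1 and PAF ∈ [0, 1); below a fixed
counterfactual PAF is negative (protective) and reported as such.

Cell-level computation is the default: PAF is concave in exposure, so
applying the chain to a region-mean exposure is not equivalent to
summing cell-level deaths (Jensen gap; the region-mean fallback exists
for runs without per-cell population and understates heterogeneous
burdens). Cells with masked exposure contribute no deaths; their
population is reported as uncovered, never redistributed.

## Synthetic study system

The generator emulates the statistical structure the analysis assumes,
with a known ground truth:

- **Predictor fields** are unit-variance Gaussian random fields
  (Gaussian-kernel-smoothed white noise — simple and dependency-light;
  only the qualitative spatial structure matters for stage testing)
  with correlation length `spatial_range_km` (default 30 km), affine
  transformed to plausible physical units, on at least three distinct
  native resolutions (0.5× to 10× the analysis cell), evolving as AR(1)
  in their native time step. The flat-field limit (infinite range) is a
  spatially constant field.
- **Latent truth**: true EC = softplus(intercept + Σ c_p·z_p + seasonal
  sinusoid + process noise), with z_p the regridded standardized
  predictors — so the truth is a function of exactly the features the
  model sees, smooth (softplus keeps it differentiable and positive,
  rather than truncation), and nonnegative by construction. The
  winter-peaking sinusoid (amplitude 0.6 on the link scale) mimics the
  heating-season cycle. Default effects load on road length (0.8),
  black carbon (0.6), emissions (0.5), absorption/total AOD
  (0.35/0.25), with negative ventilation effects (wind speed −0.3,
  boundary-layer height −0.35, visibility −0.25); the remaining
  predictors are deliberate decoys for importance-recovery tests.
- **Monitors** are placed preferentially in populous cells (matching
  how real speciation sites cluster in populated regions), snapped to
  cell centers (observations are matched to cells anyway), with
  i.i.d. Bernoulli site-day missingness (default 20%) and additive
  Gaussian observation noise (default sd 0.2 µg m⁻³; the error
  distribution of ground EC measurement is not standardised, so it is
  configuration). Observations are not clipped at zero: they are truth
  plus noise exactly, which the monitor-fidelity and signal-to-noise
  checks rely on.
- **Process vs observation noise** are separate dials: `noise_sd`
  perturbs the latent field inside the link (default 0.3), 
  `obs_noise_sd` perturbs what monitors record.
- **Population** is derived from the population-density predictor
  (clipped at 5 km⁻², times cell area), keeping monitors, weighting and
  demographics coherent with the predictor stack. Baseline mortality
  rates are drawn per region from U(0.007, 0.011) deaths·person⁻¹·yr⁻¹,
  the plausible range for adult all-cause non-accidental mortality.
- **Regions** are a nearest-seed (Voronoi) partition of the grid into
  contiguous provinces. By default the first two regions receive a
  declining linear trend in the *emission predictor* (−0.08 native
  units/yr), emulating the first-tier-city contrast where early strict
  regulation bends the emission curve; the trend lives in a feature so
  the exposure model can learn it.
- **Calendar** is real (leap days included); default reference
  conditions are a 20×20 grid, two years, 30 sites, five regions.

What the synthetic world does *not* emulate: real satellite swath
geometry and retrieval error (missingness is Bernoulli plus an optional
rectangular gap mask), correlated predictor errors, monitor siting
bias beyond population preference, or demographic trends. Passing
tests therefore demonstrate the correctness and internal consistency
of the *procedure* — regridding, OOB discipline, importance recovery,
aggregation identities, burden algebra and CI propagation — not the
accuracy of any real-world EC estimate, which depends on inputs this
package deliberately does not ship.

## Verification design and problem sizes

The acceptance suite checks each stage against an independent oracle:
direct evaluation of the risk equations on 10⁴ random parameter tuples;
a closed-form national burden under spatially constant exposure; exact
aggregation identities; a brute-force double-loop IDW implementation on
100 random instances; and truth-recovery runs on the synthetic world.
Recovery runs use 25 sites × 2 years (≈15 000 site-days) and 150–300
trees — sizes at which results are stable and a full suite runs on one
CPU in minutes.

Three verification runs configure the estimator away from the package
defaults, for methodological reasons rather than convenience:

- *Truth recovery and decoy neutrality* use greedy splits
  (`max_features=1.0`) and a truth without process noise or the
  seasonal term, but with monitor observation noise at its default.
  With p/3 feature subsampling, nearly half of all split candidates
  contain neither true driver, forcing splits on decoys and giving
  them small but systematically positive importance; with a seasonal
  cycle in the truth, any time-varying zero-coefficient predictor
  legitimately carries seasonal information and is not a pure decoy;
  and against a literally noiseless response, permuting *any* feature
  the trees ever touch strictly increases error, so an importance sd
  only becomes a meaningful null yardstick when observation noise is
  present. Importance is measured on a held-out quarter of site-days
  (the standard guard against in-sample importance bias), and decoy
  neutrality is the one-sided predictiveness test: a feature counts as
  important only if its mean importance exceeds twice its permutation
  sd, and a decoy must fail that.
- *The signal-to-noise check* (observation noise sd equal to the truth
  sd should halve the explained variance) additionally uses
  `min_samples_leaf=10`: the theoretical R² ≈ 0.5 presumes the
  regressor estimates the conditional mean, which leaf-1 trees do not —
  they interpolate noise.
- *The end-to-end truth comparison* applies one shared counterfactual
  to both the predicted and the true burden chain. Letting each chain
  resolve its own global minimum would compare minima of two surfaces —
  an extreme-value statistic the forest biases upward by shrinking the
  low tail — rather than the burden methodology itself; fixing the
  reference level across models is standard comparative-risk practice.

## Reproducibility

A single run seed is expanded into per-stage substreams by stable
hashing of stage names, so stage results do not depend on stage order.
The run manifest records the config hash, effective parameters,
per-stage wall time and SHA-256 checksums of every output file;
identical config and seed reproduce identical checksums end to end.

## Known limitations

- The log-linear exposure-response form with a single β is the
  simplest defensible choice; cause-specific, age-stratified or
  nonlinear (GEMM/IER-style) risk functions are out of scope.
- CI bounds reflect β uncertainty only.
- The burden is as good as the annual exposure surface; masked-cell
  exclusion makes coverage explicit but cannot correct it.
- IDW and areal averaging assume rectilinear planar lattices; no
  reprojection or raster-format ingestion is provided.
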