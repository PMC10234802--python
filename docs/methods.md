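# Methods

This note documents the models, algorithms, parameter choices, and known
limitations behind `cleanfleet`. It describes what the code computes and
why the defaults are what they are; every empirical number quoted here is
produced by the test suite or by `scripts/acceptance.py`.

## The problem and the unit of analysis

The package evaluates a clean-bus fleet policy at the scale of a regular
grid of square cells (300 m side by default) laid over a city. Each cell
accumulates bus vehicle-meters traveled (VMT) from the routes crossing it;
the question is whether cells whose bus service shifted more strongly
toward clean vehicles between two study years (2009 and 2014 by default)
saw systematically different changes in pollutant concentration (ΔNO,
ΔNO₂, ΔBC) than cells that did not, after adjusting for other traffic.
Coordinates are abstract planar meters: no CRS or geodesy is involved
because every computed quantity (clip lengths, containment, contiguity)
is purely Euclidean.

## Exposure construction

**Clean definitions.** A bus is a (fuel type, model year) pair, fuel in
{diesel, ULSD, CNG, hybrid}. The *broad* definition counts hybrid, CNG,
and ULSD buses as clean, plus any bus of model year ≥ 2007 (the cutoff is
inclusive: 2007 itself faces the stricter standards). The *narrow*
definition counts hybrid and CNG only and ignores vintage; it isolates
locally chosen procurement from federally driven vintage turnover. Narrow
clean is a subset of broad clean by construction, so narrow clean VMT can
never exceed broad clean VMT — a property the tests enforce per cell-year.

**Depot → route apportionment.** Every route inherits the fleet mix of
its serving depot(s); a route served by several depots takes the
*unweighted* mean of their clean fractions, regardless of depot size.
This literal "even apportionment" is a deliberate choice: absent
vehicle-level assignment data there is no defensible weighting, and the
unweighted mean is the simplest rule consistent with even apportionment.

**Annual bus counts.** Buses/year on a route = weekday trips/day × number
of weekdays + weekend trips/day × number of weekend days. The default
calendar is 261 weekdays + 104 weekend days (= 365); it is configurable
but fixed by default so simulated service totals are reproducible.

**Per-cell route lengths.** Each polyline segment is clipped against the
closed cell squares it can touch using interval (Liang–Barsky-style) slab
clipping, producing parameter intervals along the segment. Where
intervals overlap — the segment runs exactly along a shared cell edge —
the overlapping stretch is assigned to the cell with the lexicographically
smaller (row, col). This tie-break only matters on measure-zero
geometry, but it makes length conservation *exact*: the elementary
sub-intervals partition the segment, so per-cell lengths always sum to
the polyline length (tested at relative tolerance 1e-9, and
cross-checked against a brute-force 0.1 m point-sampling oracle). Any
segment leaving the grid envelope is an error rather than a silent clip.

**Units.** VMT is computed and stored in meters; reports convert to km at
output time. The log transforms in the regressions use log(x + 1) with x
in the stored unit, so coefficient scales depend on both the offset and
the unit — both are therefore written into the fit metadata.

**The clean-shift statistic.** ΔProp is the end-year clean share of a
cell's bus VMT minus the start-year clean share, a dimensionless value in
[-1, 1]. Cells with service in only one of the two years get ΔProp = 0
and `served = False`, and are grouped with never-served cells in the
descriptive tables; the served groups are defined by service in *both*
years.

## Spatial error model

The regression model is y = Xβ + u with a simultaneous autoregressive
disturbance u = λWu + ε, ε ~ N(0, σ²I), over row-standardized contiguity
weights W. Queen contiguity (edge or corner shared) is the default —
conventional for raster lattices — with rook available by configuration;
the choice is recorded in output metadata because the source analysis did
not specify its weights.

The log-likelihood is

l(β, λ, σ²) = −(n/2)·ln(2πσ²) + ln|I − λW| − (1/2σ²)·‖(I − λW)(y − Xβ)‖².

Numerical choices:

* **Log-determinant.** W is similar to the symmetric matrix
  D^-1/2 A D^-1/2 (A the binary adjacency, D its row degrees), so its
  spectrum is real; ln|I − λW| = Σ ln(1 − λω_i) from one dense symmetric
  eigendecomposition, cached per grid shape (done once even across
  hundreds of fits). The dense path is limited to n ≤ 5000, ample for the
  default 2500-cell grid. Against a dense-determinant brute-force oracle
  the likelihood agrees to ~1e-14.
* **Profiling.** For fixed λ, β(λ) is the least-squares fit of
  (I − λW)y on (I − λW)X and σ²(λ) the mean squared filtered residual;
  at λ = 0 this reproduces OLS exactly (tested to 1e-10).
* **Optimization.** Bounded Brent search of the concentrated likelihood
  over the central 99% of the open feasible interval
  (1/ω_min, 1/ω_max), xatol 1e-10. No randomness: fits are deterministic.
  An optimum pinned against the search boundary raises a convergence
  error carrying the bracketing trace rather than returning a boundary
  estimate.
* **Standard errors.** β uses the exact GLS covariance σ̂²(X̃'X̃)^-1 at λ̂
  (X̃ the filtered design); λ uses the curvature of the profile
  likelihood by central finite differences, which equals the Schur
  complement of the full observed information for the profiled
  parameters. Intervals are Wald at z = 1.96; significance is flagged at
  two-sided p < 0.05.
* **Degenerate inputs.** Rank-deficient designs are rejected naming the
  collinear columns (QR with column pivoting); dimension mismatches,
  islands in the weights (units with no neighbors), and non-finite data
  are rejected up front.
* **Reproducibility floor.** Permuting the cell order (with W permuted
  consistently) changes estimates only at the likelihood-flatness noise
  floor: near its optimum the concentrated likelihood varies by less than
  float rounding over a ~1e-7 window in λ, so agreement is asserted at
  1e-6 (λ) / 1e-7 (β), not at machine precision.

Model specifications mirror the standard adjusted-analysis ladder:
Model 1 = ΔProp only; Model 2 adds log total traffic and a truck-route
indicator; Model 3 adds log baseline (2009) bus VMT. Each is fitted per
pollutant and per clean definition. By default *all* cells enter the
regression (unserved cells with ΔProp = 0 and zero bus VMT); a
`served_only` sample rule subsets the cells and re-standardizes the
subset weights. ΔProp enters as a proportion (not a percentage); the
scale is documented here and in the metadata because coefficient
magnitudes depend on it. The traffic covariate is static (one year), as
single-year traffic measures are a common data limitation.

## Synthetic city

The generator emulates the statistical structure of the real study region
at desk scale; the defaults are the study conditions.

* **Grid.** 50 × 50 cells of 300 m (2500 cells) — large enough for stable
  SEM estimation, small enough that hundreds of simulate-and-refit cycles
  run in minutes; a stand-in for the ~9670-cell region.
* **Depots and routes.** 8 depots on random cells; routes are
  self-avoiding rook walks through cell centers (street networks are out
  of scope; per-cell intersection lengths are the only geometric quantity
  the pipeline consumes). Routes are added depot-by-depot until the
  fraction of untouched cells falls to the 39.7% target observed in the
  study region, with generous per-depot quotas so the budget almost never
  binds (realized unserved fraction 0.38–0.46 across seeds). A route
  gains a second serving depot with probability 0.25; at least one
  two-depot route is guaranteed when more than one depot exists.
* **Service frequencies.** Weekday trips/day uniform on [40, 220],
  weekend on [20, 140] (roughly 4–30 minute headways over a service day);
  year-2 frequencies scale by uniform [0.95, 1.25], echoing mild service
  growth between the study years.
* **Fleets.** Citywide totals ~5840 buses in year 1, scaled by
  5730/5838 in year 2 (the observed near-stability). Fuel-mix targets:
  hybrid 22.0% → 29.2% and CNG 12.7% → 13.1% (observed values);
  the observed "ULSD" mass is split into ULSD + conventional diesel
  (25% → 5% diesel) because an all-clean-fuel fleet would saturate the
  broad clean fraction at 1.0 in both years and degenerate ΔProp(broad)
  to zero everywhere — the split keeps both definitions informative while
  preserving the observed hybrid/CNG trajectory. Post-2007 vintage share
  16.9% → 48.7% (observed). Depot mixes are Dirichlet draws around the
  targets (concentration 15, i.e. strong across-depot heterogeneity —
  the source of spatial variation in ΔProp) recentered so the
  size-weighted citywide mix stays on target; realized citywide shares
  land within ~1.5 points of target. Counts are multinomial; exact
  integer targets are not forced.
* **Covariates.** Truck-route flags are Bernoulli(0.65) in served cells
  and Bernoulli(0.10) in unserved cells; traffic is log-normal with
  log-mean 15.3 (served) / 14.1 (unserved) and log-SD 1.2 — strongly
  right-skewed, higher where buses run, reproducing the observed
  confounding pattern and magnitudes (mean ~9e6 vs ~3e6). A
  `bus_stops_approx` column counts route vertices per cell; it is a
  deliberately rough descriptive proxy, not a stop inventory.
* **Outcomes.** Each pollutant-change surface is y = Xβ + u with
  (I − λW)u = ε solved exactly by sparse LU; X = [1, ΔProp,
  log(traffic+1), truck, log(busVMT2009+1)]. Default coefficients echo
  the published magnitudes (intercepts of a few negative ppb; a negative
  clean-shift coefficient for the nitrogen oxides, a tiny positive one
  for BC), with λ = 0.5 and σ matched to the observed outcome SDs. The
  exact coefficients and the latent u are persisted in a TruthRecord so
  recovery is testable. All generators are bit-reproducible given
  (config, seed); child seeds are spawned from the master seed.

**What the generator does not emulate.** Real street geometry, stop
spacing, ridership, deadheading, within-year service changes, measurement
error in the pollutant surfaces (treated as directly observed), and any
spatial structure in the *outcome* beyond the SAR error process.
Passing tests therefore demonstrate that the pipeline's arithmetic,
geometry, and inference are correct under a known DGP — not that the
published effect estimates are right, which would require the original
proprietary inputs.

## Simulation studies and their sizes

* **Parameter recovery / interval calibration**: 200 simulated cities
  (β = (−3.0, −0.05, −0.001, −0.03), λ = 0.5, σ = 1, Model 2 fits). The
  coverage band 90–98% is checked at 200 datasets because at 100 the
  binomial noise of a perfectly calibrated 95% interval spills outside
  the band too often for a meaningful check; the mean-λ̂ criterion
  (±0.05) is unchanged. Measured SE calibration: empirical SD / mean SE
  ≈ 1.00–1.02 per coefficient.
* **Null coverage and power**: 100 seeds each. The power study's
  clean-shift effect is −1.5: a pilot of the null distribution put the
  coefficient's sampling SD at ~0.30 on the default city, so −1.5 is a
  ~5 SD effect — sized to be reliably detectable, deliberately far larger
  than the published point estimates, whose detection at city scale is
  exactly what is *not* claimed here.
* The spatial clustering of ΔProp (cells served by one depot share its
  shift) is the reason its coefficient has a large SE relative to
  naive-OLS intuition: spatial filtering by (I − λW) removes most of the
  between-depot variance. This is a feature of the design, not a bug of
  the estimator.

## Known limitations

* The dense eigenvalue path bounds the SEM at ~5000 cells; larger grids
  would need a sparse log-determinant (not implemented — out of scope for
  the desk-scale study design).
* λ's SE from profile curvature is asymptotic; no profile-likelihood or
  bootstrap intervals for λ.
* No spatial-lag (SAR-on-y) or CAR alternatives, no REML, no robust SEs —
  deliberately matching the source analysis type.
* Group descriptive tables report no between-group tests, mirroring the
  descriptive intent of the original tables.
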