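"""Synthetic study region with a known data-generating process.

Emulates, at desk scale, the structure of a city-wide bus-fleet study:

* a square lattice of ~300 m cells;
* depots placed on the grid, each serving a handful of bus routes; routes
  are self-avoiding lattice walks through cell centers (street networks are
  out of scope — the pipeline only ever uses per-cell intersection lengths,
  which lattice walks exercise fully, including cells crossed diagonally);
* per-depot fleet rosters for the two study years, drawn by multinomial
  sampling against fuel-mix targets taken from the observed city fleet
  (ULSD-dominated, hybrid share rising from 22.0% to 29.2%, CNG stable,
  post-2007 vintage share rising from 16.9% to 48.7%, total size nearly
  stable);
* covariates that co-occur with bus service the way the descriptive tables
  show: truck routes far more prevalent and traffic volume higher (and
  log-normal, i.e. strongly right-skewed) in served cells;
* pollutant-change surfaces drawn from a spatial-error process
  y = X beta + u, (I - lambda W) u = eps, with known coefficients that are
  persisted alongside the data so parameter recovery can be tested.

Roughly 40% of cells end up with no bus service, matching the observed
39.7%. All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import ConfigError, DataError
from .exposure import (BROAD, NARROW, BusCategory, Calendar, FleetRoster, Route,
                       ServiceSchedule, build_exposure_table, route_cell_lengths)
from .grid import Grid, generate_grid
from .weights import SpatialWeights, lattice_weights

__all__ = [
    "DGPParams",
    "SimConfig",
    "Depot",
    "TruthRecord",
    "CityBundle",
    "generate_depots_and_routes",
    "generate_fleet_rosters",
    "generate_covariates",
    "generate_pollutant_change",
    "simulate_city",
]

#: Design terms of the outcome data-generating process, in order
#: (an intercept is always prepended).
DGP_TERMS = ("delta_prop_clean", "log_traffic", "truck_route", "log_bus_vmt_2009")


@dataclass(frozen=True)
class DGPParams:
    """Spatial-error DGP for one pollutant-change surface.

    ``beta`` is (intercept, *DGP_TERMS); ``lam`` the spatial autoregressive
    parameter, strictly inside (-1, 1); ``sigma`` the innovation SD.
    """

    beta: Tuple[float, ...]
    lam: float = 0.5
    sigma: float = 1.0

    def __post_init__(self):
        if not (-1.0 < self.lam < 1.0):
            raise ConfigError(f"lambda must lie strictly inside (-1, 1), got {self.lam}")
        if self.sigma < 0:
            raise ConfigError(f"sigma must be nonnegative, got {self.sigma}")


def _default_dgps() -> Dict[str, DGPParams]:
    # Coefficient magnitudes echo the published adjusted models: pollutant
    # declines of a few ppb, a negative clean-shift effect for the nitrogen
    # oxides, a small positive one for black carbon.
    return {
        "d_no": DGPParams(beta=(-3.0, -0.05, -0.001, -0.03, -0.002), lam=0.5, sigma=1.0),
        "d_no2": DGPParams(beta=(-3.0, -0.011, -0.00014, 0.003, -0.0002), lam=0.5, sigma=0.9),
        "d_bc": DGPParams(beta=(-0.18, 7.1e-05, -1.8e-07, 3.3e-05, 1.5e-06), lam=0.5, sigma=0.025),
    }


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic study region.

    Defaults describe the emulated study conditions: a 50 x 50 grid of
    300 m cells (desk-scale stand-in for the ~9700-cell city), 8 depots
    with generous route quotas (route growth stops once the served-cell
    target is reached), ~39.7% of cells unserved, fleet-mix targets from
    the observed 2009/2014 fleet, and service/traffic scales echoing the
    descriptive tables.
    """

    nrows: int = 50
    ncols: int = 50
    cell_size: float = 300.0

    n_depots: int = 8
    n_routes: int = 260
    routes_per_depot_range: Tuple[int, int] = (18, 34)
    route_length_range: Tuple[int, int] = (30, 80)  # cells per walk
    p_second_depot: float = 0.25

    # trips/day; year-2 frequency drifts mildly upward, as service grew
    weekday_trips_range: Tuple[float, float] = (40.0, 220.0)
    weekend_trips_range: Tuple[float, float] = (20.0, 140.0)
    year2_frequency_scale_range: Tuple[float, float] = (0.95, 1.25)

    years: Tuple[int, int] = (2009, 2014)
    # per-depot fleets sized so the citywide total matches the observed
    # ~5840-bus fleet even though the depot count is scaled down
    fleet_per_depot_range: Tuple[int, int] = (650, 810)
    year2_fleet_scale: float = 5730.0 / 5838.0  # near-stable total fleet
    # citywide fuel-mix targets; depot mixes are Dirichlet-perturbed around
    # these (concentration below) so the clean fraction varies across depots
    fuel_shares: Tuple[Tuple[str, float, float], ...] = (
        # (fuel, year-1 share, year-2 share)
        ("diesel", 0.250, 0.050),
        ("ULSD", 0.403, 0.527),
        ("CNG", 0.127, 0.131),
        ("hybrid", 0.220, 0.292),
    )
    post2007_share: Tuple[float, float] = (0.169, 0.487)
    depot_mix_concentration: float = 15.0
    pre_vintage_range: Tuple[int, int] = (1997, 2006)
    vintage_cutoff: int = 2007

    fraction_cells_unserved: float = 0.397
    p_truck_served: float = 0.65
    p_truck_unserved: float = 0.10
    traffic_logmean_served: float = 15.3
    traffic_logmean_unserved: float = 14.1
    traffic_logsd: float = 1.2

    calendar: Calendar = field(default_factory=Calendar)
    dgp: Optional[Dict[str, DGPParams]] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.nrows < 2 or self.ncols < 2 or self.cell_size <= 0:
            raise ConfigError("grid dimensions must be >= 2 and cell_size positive")
        if self.n_depots < 1:
            raise ConfigError("n_depots must be >= 1")
        if self.n_routes < 1:
            raise ConfigError("n_routes must be >= 1")
        for year_idx in (1, 2):
            tot = sum(row[year_idx] for row in self.fuel_shares)
            if abs(tot - 1.0) > 1e-6:
                raise ConfigError(
                    f"fuel shares for year {self.years[year_idx - 1]} sum to {tot:.4f}, not 1")
        for p in (self.fraction_cells_unserved, self.p_truck_served,
                  self.p_truck_unserved, *self.post2007_share):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"proportion {p} outside [0, 1]")

    def dgps(self) -> Dict[str, DGPParams]:
        return dict(self.dgp) if self.dgp is not None else _default_dgps()

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class Depot:
    depot_id: str
    row: int
    col: int
    x: float
    y: float


@dataclass(frozen=True)
class TruthRecord:
    """The DGP actually used for one simulated surface, for recovery tests."""

    pollutant: str
    terms: Tuple[str, ...]
    beta: Tuple[float, ...]
    lam: float
    sigma: float
    latent_u: np.ndarray  # per-cell spatially correlated disturbance


@dataclass
class CityBundle:
    """Everything one simulated city produces."""

    config: SimConfig
    seed: int
    grid: Grid
    depots: Tuple[Depot, ...]
    routes: Tuple[Route, ...]
    rosters: Dict[Tuple[str, int], FleetRoster]
    covariates: pd.DataFrame  # cell_id-indexed: truck_route, traffic_vmt, bus_stops_approx
    exposure: pd.DataFrame    # output of build_exposure_table
    outcomes: pd.DataFrame    # cell_id-indexed d_no / d_no2 / d_bc
    truth: Dict[str, TruthRecord]


# --------------------------------------------------------------------------- #
# depots and routes


def _self_avoiding_walk(grid: Grid, start: Tuple[int, int], n_cells: int, rng):
    """Rook-step self-avoiding walk over cells; stops early at dead ends."""
    path = [start]
    visited = {start}
    r, c = start
    for _ in range(n_cells - 1):
        options = [(r + dr, c + dc) for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0))
                   if 0 <= r + dr < grid.nrows and 0 <= c + dc < grid.ncols
                   and (r + dr, c + dc) not in visited]
        if not options:
            break
        r, c = options[rng.integers(len(options))]
        path.append((r, c))
        visited.add((r, c))
    return path


def generate_depots_and_routes(grid: Grid, config: SimConfig, seed=None):
    """Place depots and grow routes until the served-cell target is met.

    Routes are added depot by depot (respecting each depot's drawn route
    quota) until either the fraction of cells untouched by any route drops
    to the configured target or the route budget ``n_routes`` is exhausted,
    so the realized unserved fraction tracks the target to within about one
    route's footprint. Each route gets a second serving depot with
    probability ``p_second_depot`` (the nearest other depot); at least one
    two-depot route is guaranteed whenever more than one depot exists.
    """
    if grid.n_cells == 0:
        raise DataError("empty grid")
    rng = np.random.default_rng(_require_seed(config, seed))
    n_cells = grid.n_cells

    depot_cells = rng.choice(n_cells, size=min(config.n_depots, n_cells), replace=False)
    depots = []
    for k, cid in enumerate(sorted(int(c) for c in depot_cells)):
        row, col = grid.rowcol(cid)
        x, y = grid.cell_center(row, col)
        depots.append(Depot(depot_id=f"D{k:02d}", row=row, col=col, x=x, y=y))
    depots = tuple(depots)

    quotas = rng.integers(config.routes_per_depot_range[0],
                          config.routes_per_depot_range[1] + 1, size=len(depots))
    served = np.zeros(n_cells, dtype=bool)
    target_served = (1.0 - config.fraction_cells_unserved) * n_cells
    routes = []
    order = list(rng.permutation(len(depots)))
    qi = 0
    while len(routes) < config.n_routes and served.sum() < target_served:
        # next depot with quota remaining, round-robin
        for _ in range(len(depots)):
            d = order[qi % len(depots)]
            qi += 1
            if quotas[d] > 0:
                break
        else:
            break  # all quotas exhausted
        quotas[d] -= 1
        depot = depots[d]
        length = int(rng.integers(config.route_length_range[0],
                                  config.route_length_range[1] + 1))
        path = _self_avoiding_walk(grid, (depot.row, depot.col), length, rng)
        if len(path) < 2:
            continue
        depot_ids = [depot.depot_id]
        if len(depots) > 1 and rng.random() < config.p_second_depot:
            others = [e for e in depots if e.depot_id != depot.depot_id]
            nearest = min(others, key=lambda e: (e.x - depot.x) ** 2 + (e.y - depot.y) ** 2)
            depot_ids.append(nearest.depot_id)
        coords = tuple(grid.cell_center(r, c) for r, c in path)
        schedules = _draw_schedules(f"R{len(routes):03d}", config, rng)
        routes.append(Route(route_id=f"R{len(routes):03d}", coords=coords,
                            depot_ids=tuple(depot_ids), schedules=schedules))
        for r, c in path:
            served[grid.cell_id(r, c)] = True

    if len(depots) > 1 and routes and not any(len(r.depot_ids) > 1 for r in routes):
        r0 = routes[0]
        home = next(e for e in depots if e.depot_id == r0.depot_ids[0])
        others = [e for e in depots if e.depot_id != home.depot_id]
        nearest = min(others, key=lambda e: (e.x - home.x) ** 2 + (e.y - home.y) ** 2)
        routes[0] = Route(route_id=r0.route_id, coords=r0.coords,
                          depot_ids=(*r0.depot_ids, nearest.depot_id),
                          schedules=r0.schedules)
    return depots, tuple(routes)


def _draw_schedules(route_id: str, config: SimConfig, rng):
    y1, y2 = config.years
    wd = rng.uniform(*config.weekday_trips_range)
    we = rng.uniform(*config.weekend_trips_range)
    scale = rng.uniform(*config.year2_frequency_scale_range)
    return {
        y1: ServiceSchedule(route_id, y1, wd, we),
        y2: ServiceSchedule(route_id, y2, wd * scale, we * scale),
    }


# --------------------------------------------------------------------------- #
# rosters


def _recenter_mixes(mix, targets, weights):
    """Shift per-depot fuel mixes so their weighted mean equals ``targets``.

    Entries whose target is zero stay zero; others are floored at 0.005 and
    rows renormalized, so recentring only approximately survives extreme
    draws but in practice holds to well under a percentage point.
    """
    dev = targets - np.average(mix, axis=0, weights=weights)
    out = np.where(targets > 0, np.maximum(mix + dev, 0.005), 0.0)
    return out / out.sum(axis=1, keepdims=True)


def generate_fleet_rosters(depots, config: SimConfig, seed=None):
    """Multinomial fleet rosters per (depot, year).

    Depot fuel mixes are Dirichlet perturbations of the citywide targets
    (concentration ``depot_mix_concentration``), so clean fractions differ
    across depots while citywide shares stay within a couple of percentage
    points of target. Model years are drawn independently of fuel: with the
    year's post-cutoff probability a vintage in [cutoff, year], else one in
    ``pre_vintage_range``. Depot sizes are stable across years up to the
    configured citywide scale factor.
    """
    rng = np.random.default_rng(_require_seed(config, seed))
    fuels = [row[0] for row in config.fuel_shares]
    rosters: Dict[Tuple[str, int], FleetRoster] = {}
    sizes = np.array([int(rng.integers(config.fleet_per_depot_range[0],
                                       config.fleet_per_depot_range[1] + 1))
                      for _ in depots])
    c = config.depot_mix_concentration
    for year_idx, year in enumerate(config.years):
        shares = np.array([row[1 + year_idx] for row in config.fuel_shares])
        p_post = config.post2007_share[year_idx]
        n_year = sizes if year_idx == 0 else np.round(
            sizes * config.year2_fleet_scale).astype(int)
        # Dirichlet depot mixes recentered onto the citywide targets: depots
        # differ strongly in fleet mix, yet the size-weighted citywide shares
        # stay on target up to multinomial noise
        alpha = np.where(shares > 0, shares * c, 1e-9)
        mix = _recenter_mixes(rng.dirichlet(alpha, size=len(depots)), shares, n_year)
        post = rng.beta(max(p_post * c, 1e-9), max((1 - p_post) * c, 1e-9),
                        size=len(depots))
        post = np.clip(post + (p_post - np.average(post, weights=n_year)), 0.0, 1.0)
        for d_idx, depot in enumerate(depots):
            n_buses = int(n_year[d_idx])
            p_post_depot = float(post[d_idx])
            fuel_counts = rng.multinomial(n_buses, mix[d_idx])
            counts: Dict[BusCategory, int] = {}
            for fuel, cnt in zip(fuels, fuel_counts):
                if cnt == 0:
                    continue
                n_post = rng.binomial(cnt, p_post_depot)
                for n_k, lo, hi in ((n_post, config.vintage_cutoff, year),
                                    (cnt - n_post, *config.pre_vintage_range)):
                    if n_k == 0:
                        continue
                    vintages = rng.integers(lo, hi + 1, size=n_k)
                    for v in vintages:
                        cat = BusCategory(fuel, int(v))
                        counts[cat] = counts.get(cat, 0) + 1
            rosters[(depot.depot_id, year)] = FleetRoster(depot.depot_id, year, counts)
    return rosters


# --------------------------------------------------------------------------- #
# covariates


def generate_covariates(grid: Grid, routes, config: SimConfig, seed=None) -> pd.DataFrame:
    """Truck-route flags and total-traffic VMT per cell.

    Both co-occur with bus service: served cells draw the truck flag with
    the higher Bernoulli probability and traffic from the log-normal with
    the higher log-mean, reproducing the confounding structure of the
    descriptive tables. Also emits ``bus_stops_approx``, a deliberately
    rough bus-stop proxy: the count of route polyline vertices in the cell.
    """
    rng = np.random.default_rng(_require_seed(config, seed))
    n = grid.n_cells
    served = np.zeros(n, dtype=bool)
    stops = np.zeros(n, dtype=int)
    for route in routes:
        for cell_id in route_cell_lengths(route, grid):
            served[cell_id] = True
        for x, y in route.coords:
            col = min(int(x // grid.cell_size), grid.ncols - 1)
            row = min(int(y // grid.cell_size), grid.nrows - 1)
            stops[grid.cell_id(row, col)] += 1
    p_truck = np.where(served, config.p_truck_served, config.p_truck_unserved)
    truck = rng.random(n) < p_truck
    logmean = np.where(served, config.traffic_logmean_served,
                       config.traffic_logmean_unserved)
    traffic = np.exp(rng.normal(logmean, config.traffic_logsd))
    return pd.DataFrame(
        {"truck_route": truck.astype(int), "traffic_vmt": traffic,
         "bus_stops_approx": stops},
        index=pd.RangeIndex(n, name="cell_id"),
    )


# --------------------------------------------------------------------------- #
# outcome surfaces


def generate_pollutant_change(X, weights: SpatialWeights, beta, lam, sigma, seed,
                              pollutant: str = "y", terms=DGP_TERMS) -> TruthRecord:
    """Draw one change surface from the spatial-error process.

    y = X beta + u with (I - lam W) u = eps, eps iid N(0, sigma^2); u is
    obtained by an exact sparse solve of (I - lam W) u = eps. Returns the
    TruthRecord (which carries u); the observable surface is
    ``X @ beta + truth.latent_u``.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float).ravel()
    if not (-1.0 < lam < 1.0):
        raise ConfigError(f"lambda must lie strictly inside (-1, 1), got {lam}")
    if sigma < 0:
        raise ConfigError("sigma must be nonnegative")
    if X.ndim != 2 or X.shape[0] != weights.n:
        raise DataError(f"design matrix rows ({X.shape[0]}) != weights size ({weights.n})")
    if X.shape[1] != beta.shape[0]:
        raise DataError(f"beta length {beta.shape[0]} != design width {X.shape[1]}")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, 1.0, size=weights.n) * sigma
    if lam == 0.0:
        u = eps
    else:
        B = sp.identity(weights.n, format="csc") - lam * sp.csc_matrix(weights.W)
        u = splu(B).solve(eps)
    return TruthRecord(pollutant=pollutant, terms=tuple(terms), beta=tuple(beta),
                       lam=float(lam), sigma=float(sigma), latent_u=u)


def dgp_design(exposure: pd.DataFrame, covariates: pd.DataFrame, years,
               definition: str = "broad") -> np.ndarray:
    """Design matrix [1, *DGP_TERMS] used by the outcome DGP (meters, log1p)."""
    y1 = years[0]
    n = len(covariates)
    X = np.column_stack([
        np.ones(n),
        exposure[f"delta_prop_clean_{definition}"].to_numpy(),
        np.log1p(covariates["traffic_vmt"].to_numpy()),
        covariates["truck_route"].to_numpy(dtype=float),
        np.log1p(exposure[f"total_vmt_{y1}"].to_numpy()),
    ])
    return X


# --------------------------------------------------------------------------- #
# one-call simulation


def _require_seed(config: SimConfig, seed):
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ConfigError("no seed supplied: simulation refuses implicit randomness")
    return int(seed)


def simulate_city(config: SimConfig = SimConfig(), seed=None,
                  contiguity: str = "queen") -> CityBundle:
    """Generate a complete synthetic city bundle.

    Component generators receive independent child seeds spawned from the
    master seed, so the whole bundle is reproducible bit-for-bit.
    """
    master = _require_seed(config, seed)
    dgps = sorted(config.dgps().items())
    ss = np.random.SeedSequence(master)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4 + len(dgps))]

    grid = generate_grid(config.nrows, config.ncols, config.cell_size)
    depots, routes = generate_depots_and_routes(grid, config, seed=child[0])
    rosters = generate_fleet_rosters(depots, config, seed=child[1])
    covariates = generate_covariates(grid, routes, config, seed=child[2])
    exposure = build_exposure_table(routes, rosters, grid, config.years,
                                    definitions=(BROAD, NARROW),
                                    calendar=config.calendar)
    weights = lattice_weights(config.nrows, config.ncols, contiguity)
    X = dgp_design(exposure, covariates, config.years)
    outcomes = pd.DataFrame(index=covariates.index)
    truth: Dict[str, TruthRecord] = {}
    for k, (pollutant, params) in enumerate(dgps):
        rec = generate_pollutant_change(X, weights, params.beta, params.lam,
                                        params.sigma, seed=child[4 + k],
                                        pollutant=pollutant)
        outcomes[pollutant] = X @ np.asarray(params.beta) + rec.latent_u
        truth[pollutant] = rec
    return CityBundle(config=config, seed=master, grid=grid, depots=depots,
                      routes=routes, rosters=rosters, covariates=covariates,
                      exposure=exposure, outcomes=outcomes, truth=truth)
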