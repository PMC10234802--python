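"""Bus-service exposure construction.

This module turns depot fleet rosters, route geometry, and service
frequencies into per-cell exposures:

* classification of individual buses as "clean" under a broad definition
  (hybrid-electric, CNG, or ULSD fuel, or any bus of model year 2007 or
  later, which faces stricter federal emissions standards) or a narrow one
  (hybrid-electric and CNG only, isolating locally driven procurement);
* depot -> route apportionment: every route served by a depot inherits the
  depot's fleet mix; routes served by several depots average their depots'
  clean fractions with equal weight;
* annual bus vehicle-meters-traveled (VMT) per grid cell: the route length
  falling inside the cell times the number of buses running the route per
  year (weekday frequency x weekday count + weekend frequency x weekend
  count);
* the clean-shift statistic Delta-Prop: the end-year clean share of a
  cell's bus VMT minus the start-year clean share.

VMT is computed and stored in meters throughout; reports convert to km at
output time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .errors import ConfigError, DataError
from .grid import Grid

__all__ = [
    "FUEL_TYPES",
    "BusCategory",
    "CleanDefinition",
    "BROAD",
    "NARROW",
    "FleetRoster",
    "ServiceSchedule",
    "Calendar",
    "Route",
    "is_clean",
    "depot_clean_fraction",
    "route_clean_fraction",
    "annual_bus_count",
    "route_cell_lengths",
    "cell_bus_vmt",
    "delta_prop_clean",
    "build_exposure_table",
]

FUEL_TYPES = ("diesel", "ULSD", "CNG", "hybrid")
MODEL_YEAR_RANGE = (1985, 2020)


@dataclass(frozen=True)
class BusCategory:
    """A bus type: fuel technology plus model year."""

    fuel_type: str
    model_year: int

    def __post_init__(self):
        if self.fuel_type not in FUEL_TYPES:
            raise DataError(
                f"unknown fuel type {self.fuel_type!r}; expected one of {FUEL_TYPES}"
            )
        lo, hi = MODEL_YEAR_RANGE
        if not (lo <= int(self.model_year) <= hi):
            raise DataError(
                f"model year {self.model_year} outside plausible range {MODEL_YEAR_RANGE}"
            )


@dataclass(frozen=True)
class CleanDefinition:
    """Which buses count as clean.

    ``clean_fuels`` are clean regardless of age; if ``vintage_cutoff`` is
    set, any bus with model year >= the cutoff is clean regardless of fuel.
    """

    name: str
    clean_fuels: frozenset
    vintage_cutoff: Optional[int] = None


#: Hybrid, CNG, or ULSD fuel, or any model year 2007+ (stricter standards).
BROAD = CleanDefinition("broad", frozenset({"hybrid", "CNG", "ULSD"}), 2007)
#: Hybrid and CNG only — the locally driven procurement choices.
NARROW = CleanDefinition("narrow", frozenset({"hybrid", "CNG"}), None)

DEFINITIONS = {"broad": BROAD, "narrow": NARROW}


@dataclass(frozen=True)
class FleetRoster:
    """Bus counts at one depot in one year, keyed by :class:`BusCategory`."""

    depot_id: str
    year: int
    counts: Mapping[BusCategory, int]

    def __post_init__(self):
        for cat, cnt in self.counts.items():
            if cnt < 0:
                raise DataError(f"negative count {cnt} for {cat} at depot {self.depot_id}")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class ServiceSchedule:
    """Daily trip frequencies of a route in one year."""

    route_id: str
    year: int
    weekday_trips_per_day: float
    weekend_trips_per_day: float

    def __post_init__(self):
        if self.weekday_trips_per_day < 0 or self.weekend_trips_per_day < 0:
            raise DataError(f"negative trip frequency on route {self.route_id}")


@dataclass(frozen=True)
class Calendar:
    """Weekday/weekend day counts of one service year (default 261 + 104)."""

    n_weekdays: int = 261
    n_weekend_days: int = 104

    def __post_init__(self):
        total = self.n_weekdays + self.n_weekend_days
        if total not in (365, 366):
            raise ConfigError(f"calendar days must sum to 365 or 366, got {total}")


@dataclass(frozen=True)
class Route:
    """A bus route: polyline geometry, serving depots, per-year schedules."""

    route_id: str
    coords: tuple  # ((x, y), ...) vertices in meters
    depot_ids: tuple
    schedules: Mapping[int, ServiceSchedule] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.coords) < 2:
            raise DataError(f"route {self.route_id} needs at least 2 vertices")
        if len(self.depot_ids) == 0:
            raise DataError(f"route {self.route_id} has no serving depot")

    @property
    def geometry(self) -> LineString:
        return LineString(self.coords)

    @property
    def length(self) -> float:
        c = np.asarray(self.coords)
        return float(np.hypot(*(c[1:] - c[:-1]).T).sum())


# ---------------------------------------------------------------------------
# classification and apportionment


def is_clean(category: BusCategory, definition: CleanDefinition) -> bool:
    """Is this bus clean under the given definition?

    True when its fuel is in the definition's clean set, or when the
    definition carries a vintage cutoff and the model year meets it.
    """
    if category.fuel_type not in FUEL_TYPES:
        raise DataError(f"unknown fuel type {category.fuel_type!r}")
    if category.fuel_type in definition.clean_fuels:
        return True
    return definition.vintage_cutoff is not None and category.model_year >= definition.vintage_cutoff


def depot_clean_fraction(roster: FleetRoster, definition: CleanDefinition) -> float:
    """Share of a depot's buses that are clean under ``definition``."""
    total = roster.total
    if total == 0:
        raise DataError(
            f"depot {roster.depot_id} has an empty roster in {roster.year}; "
            "a depot with zero buses cannot serve routes"
        )
    clean = sum(cnt for cat, cnt in roster.counts.items() if is_clean(cat, definition))
    return clean / total


def route_clean_fraction(route: Route, rosters_by_depot, year: int,
                         definition: CleanDefinition) -> float:
    """Clean share of service on a route: the unweighted mean of its serving
    depots' clean fractions (buses are apportioned evenly across depots)."""
    fracs = []
    for depot_id in route.depot_ids:
        roster = _lookup_roster(rosters_by_depot, depot_id, year)
        if roster is None:
            raise DataError(
                f"no fleet roster for depot {depot_id} in year {year} "
                f"(required by route {route.route_id})"
            )
        fracs.append(depot_clean_fraction(roster, definition))
    return float(np.mean(fracs))


def _lookup_roster(rosters, depot_id, year):
    """Accept {(depot, year): roster} or {depot: {year: roster}} layouts."""
    if (depot_id, year) in rosters:
        return rosters[(depot_id, year)]
    by_year = rosters.get(depot_id)
    if isinstance(by_year, Mapping):
        return by_year.get(year)
    return None


def annual_bus_count(schedule: ServiceSchedule, calendar: Calendar = Calendar()) -> float:
    """Buses per year on a route from its weekday and weekend frequencies."""
    return (schedule.weekday_trips_per_day * calendar.n_weekdays
            + schedule.weekend_trips_per_day * calendar.n_weekend_days)


# ---------------------------------------------------------------------------
# geometry: clipping route polylines to grid cells


def _slab_interval(p, d, lo, hi, t0, t1):
    """Intersect the running parameter interval with one closed slab lo<=p+t*d<=hi."""
    if abs(d) < 1e-12:  # no meaningful movement along this axis
        if p < lo or p > hi:
            return None
        return t0, t1
    ta = (lo - p) / d
    tb = (hi - p) / d
    if ta > tb:
        ta, tb = tb, ta
    t0 = max(t0, ta)
    t1 = min(t1, tb)
    if t0 > t1:
        return None
    return t0, t1


def route_cell_lengths(route, grid: Grid) -> dict:
    """Length of a route polyline inside each grid cell, in meters.

    Each polyline segment is clipped against the closed cell squares it can
    touch, yielding parameter intervals along the segment. Where intervals
    overlap — the segment runs exactly along a shared cell edge or corner —
    the overlapping stretch is assigned to the cell with the
    lexicographically smaller (row, col), so total length is conserved
    exactly. Cells the route does not touch are absent from the result.

    Raises :class:`DataError` when any part of the polyline leaves the grid
    envelope.
    """
    coords = np.asarray(route.coords if hasattr(route, "coords") else route, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) < 2:
        raise DataError("route must be a polyline of >= 2 (x, y) vertices")
    s = grid.cell_size
    lengths: dict = {}
    for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
        if not (grid.contains_point(x0, y0) and grid.contains_point(x1, y1)):
            raise DataError(
                f"route segment ({x0:g},{y0:g})-({x1:g},{y1:g}) leaves the grid envelope "
                f"{grid.bounds}"
            )
        dx, dy = x1 - x0, y1 - y0
        seglen = math.hypot(dx, dy)
        if seglen == 0.0:
            continue
        # candidate cells from the segment's bounding box, padded one cell so
        # boundary-riding segments see the neighbors on both sides
        cmin = max(0, int(math.floor(min(x0, x1) / s)) - 1)
        cmax = min(grid.ncols - 1, int(math.floor(max(x0, x1) / s)) + 1)
        rmin = max(0, int(math.floor(min(y0, y1) / s)) - 1)
        rmax = min(grid.nrows - 1, int(math.floor(max(y0, y1) / s)) + 1)
        intervals = []  # (t0, t1, (row, col))
        for row in range(rmin, rmax + 1):
            for col in range(cmin, cmax + 1):
                hit = _slab_interval(x0, dx, col * s, (col + 1) * s, 0.0, 1.0)
                if hit is None:
                    continue
                hit = _slab_interval(y0, dy, row * s, (row + 1) * s, *hit)
                if hit is None or hit[1] - hit[0] <= 0.0:
                    continue
                intervals.append((hit[0], hit[1], (row, col)))
        if not intervals:
            raise DataError("route segment not covered by any grid cell")
        # resolve overlaps on elementary sub-intervals: lexicographically
        # smallest (row, col) wins
        cuts = sorted({t for t0, t1, _ in intervals for t in (t0, t1)})
        covered = 0.0
        for a, b in zip(cuts[:-1], cuts[1:]):
            if b <= a:
                continue
            owners = [rc for t0, t1, rc in intervals if t0 <= a and b <= t1]
            if not owners:
                raise DataError("route segment leaves the grid envelope between cells")
            rc = min(owners)
            cell_id = rc[0] * grid.ncols + rc[1]
            lengths[cell_id] = lengths.get(cell_id, 0.0) + (b - a) * seglen
            covered += b - a
        if not math.isclose(covered, 1.0, rel_tol=1e-9, abs_tol=1e-12):
            raise DataError("route segment leaves the grid envelope")
    return lengths


# ---------------------------------------------------------------------------
# per-cell VMT and the clean-shift statistic


def cell_bus_vmt(routes: Sequence[Route], rosters, grid: Grid, year: int,
                 definitions=(BROAD, NARROW),
                 calendar: Calendar = Calendar()) -> pd.DataFrame:
    """Per-cell total and clean bus VMT (meters) for one year.

    For each route, VMT in a cell is the route length inside the cell times
    the route's annual bus count; the clean share of that VMT is the route's
    clean fraction. Contributions are additive over routes. Returns a frame
    indexed by cell_id over all grid cells (zeros where unserved) with a
    ``total_vmt`` column and one ``clean_vmt_<name>`` column per definition.
    """
    n = grid.n_cells
    total = np.zeros(n)
    clean = {d.name: np.zeros(n) for d in definitions}
    for route in routes:
        sched = route.schedules.get(year)
        if sched is None:
            raise DataError(f"route {route.route_id} has no schedule for year {year}")
        buses = annual_bus_count(sched, calendar)
        fracs = {d.name: route_clean_fraction(route, rosters, year, d) for d in definitions}
        for cell_id, length in route_cell_lengths(route, grid).items():
            vmt = length * buses
            total[cell_id] += vmt
            for name, frac in fracs.items():
                clean[name][cell_id] += vmt * frac
    out = pd.DataFrame({"total_vmt": total}, index=pd.RangeIndex(n, name="cell_id"))
    for name, arr in clean.items():
        out[f"clean_vmt_{name}"] = arr
    return out


def delta_prop_clean(clean_y1: float, total_y1: float,
                     clean_y2: float, total_y2: float) -> tuple:
    """Clean-shift statistic for one cell and one definition.

    Returns ``(delta, served)`` where ``delta`` is the end-year clean
    proportion of bus VMT minus the start-year clean proportion — a value
    in [-1, 1] — and ``served`` flags whether the cell had bus service in
    both years. Cells without service in both years get ``(0.0, False)``.
    """
    if total_y1 > 0 and total_y2 > 0:
        return clean_y2 / total_y2 - clean_y1 / total_y1, True
    return 0.0, False


def build_exposure_table(routes, rosters, grid: Grid, years,
                         definitions=(BROAD, NARROW),
                         calendar: Calendar = Calendar()) -> pd.DataFrame:
    """Full per-cell exposure table across the two study years.

    Columns: ``total_vmt_<year>`` and ``clean_vmt_<def>_<year>`` in meters,
    ``delta_prop_clean_<def>`` per definition, and a ``served`` flag true
    iff the cell has positive bus VMT in both years.
    """
    y1, y2 = years
    t1 = cell_bus_vmt(routes, rosters, grid, y1, definitions, calendar)
    t2 = cell_bus_vmt(routes, rosters, grid, y2, definitions, calendar)
    out = pd.DataFrame(index=t1.index)
    out[f"total_vmt_{y1}"] = t1["total_vmt"]
    out[f"total_vmt_{y2}"] = t2["total_vmt"]
    for d in definitions:
        out[f"clean_vmt_{d.name}_{y1}"] = t1[f"clean_vmt_{d.name}"]
        out[f"clean_vmt_{d.name}_{y2}"] = t2[f"clean_vmt_{d.name}"]
    served = (out[f"total_vmt_{y1}"] > 0) & (out[f"total_vmt_{y2}"] > 0)
    out["served"] = served
    for d in definitions:
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = (out[f"clean_vmt_{d.name}_{y2}"] / out[f"total_vmt_{y2}"]
                     - out[f"clean_vmt_{d.name}_{y1}"] / out[f"total_vmt_{y1}"])
        out[f"delta_prop_clean_{d.name}"] = np.where(served, delta, 0.0)
    return out
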