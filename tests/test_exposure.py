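"""Exposure construction: clean classification, apportionment, VMT, Delta-Prop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cleanfleet import (BROAD, NARROW, BusCategory, Calendar, DataError,
                        FleetRoster, Route, ServiceSchedule, annual_bus_count,
                        cell_bus_vmt, delta_prop_clean, depot_clean_fraction,
                        generate_grid, is_clean, route_cell_lengths,
                        route_clean_fraction)


def roster(depot="D", year=2009, **buses):
    """roster(hybrid_2010=5, diesel_2001=3) -> FleetRoster."""
    counts = {}
    for key, cnt in buses.items():
        fuel, yr = key.rsplit("_", 1)
        counts[BusCategory(fuel, int(yr))] = cnt
    return FleetRoster(depot, year, counts)


class TestCleanClassification:
    @pytest.mark.parametrize("fuel,year,definition,expected", [
        ("diesel", 2008, BROAD, True),    # post-2007 vintage counts as clean
        ("diesel", 2008, NARROW, False),  # narrow ignores vintage
        ("ULSD", 2003, BROAD, True),
        ("ULSD", 2003, NARROW, False),
        ("diesel", 2006, BROAD, False),
        ("diesel", 2007, BROAD, True),    # cutoff year itself is clean
        ("hybrid", 1999, NARROW, True),
        ("CNG", 2001, NARROW, True),
    ])
    def test_definitions(self, fuel, year, definition, expected):
        assert is_clean(BusCategory(fuel, year), definition) is expected

    def test_unknown_fuel_rejected(self):
        with pytest.raises(DataError):
            BusCategory("electric", 2010)

    def test_narrow_clean_implies_broad_clean(self):
        for fuel in ("diesel", "ULSD", "CNG", "hybrid"):
            for year in (1995, 2006, 2007, 2015):
                cat = BusCategory(fuel, year)
                if is_clean(cat, NARROW):
                    assert is_clean(cat, BROAD)


class TestDepotAndRouteFractions:
    def test_half_clean(self):
        r = roster(hybrid_2005=50, diesel_2005=50)
        assert depot_clean_fraction(r, NARROW) == 0.5

    def test_all_clean(self):
        assert depot_clean_fraction(roster(hybrid_2010=7), NARROW) == 1.0

    def test_mixed_broad(self):
        r = roster(CNG_2005=1, ULSD_2005=2, diesel_2001=1)
        assert depot_clean_fraction(r, BROAD) == 0.75

    def test_empty_roster_is_an_error(self):
        with pytest.raises(DataError, match="zero buses"):
            depot_clean_fraction(FleetRoster("D", 2009, {}), BROAD)

    @pytest.mark.parametrize("fracs,expected", [
        ((0.2, 0.6), 0.4),
        ((0.5,), 0.5),
        ((0.0, 0.0, 1.0), 1 / 3),
    ])
    def test_even_apportionment_over_depots(self, fracs, expected):
        rosters = {}
        for k, f in enumerate(fracs):
            n_clean = int(round(f * 100))
            rosters[(f"D{k}", 2009)] = roster(
                f"D{k}", hybrid_2010=n_clean, diesel_2001=100 - n_clean)
        route = Route("R1", ((0, 0), (1, 1)), tuple(f"D{k}" for k in range(len(fracs))))
        assert route_clean_fraction(route, rosters, 2009, NARROW) == pytest.approx(expected)

    def test_missing_roster_names_depot_and_year(self):
        route = Route("R1", ((0, 0), (1, 1)), ("D9",))
        with pytest.raises(DataError, match="D9.*2014"):
            route_clean_fraction(route, {}, 2014, BROAD)


class TestAnnualBusCount:
    @pytest.mark.parametrize("wd,we,expected", [(10, 5, 3130), (0, 0, 0), (1, 1, 365)])
    def test_counts(self, wd, we, expected):
        s = ServiceSchedule("R", 2009, wd, we)
        assert annual_bus_count(s, Calendar(261, 104)) == expected

    def test_negative_frequency_rejected(self):
        with pytest.raises(DataError):
            ServiceSchedule("R", 2009, -1, 0)

    def test_calendar_must_cover_a_year(self):
        from cleanfleet import ConfigError

        with pytest.raises(ConfigError):
            Calendar(200, 100)


class TestRouteCellLengths:
    def test_straight_crossing_two_cells(self):
        g = generate_grid(2, 2, 300)
        lengths = route_cell_lengths(((0.0, 150.0), (600.0, 150.0)), g)
        assert lengths == pytest.approx({g.cell_id(0, 0): 300.0, g.cell_id(0, 1): 300.0})

    def test_diagonal_of_one_cell(self):
        g = generate_grid(2, 2, 300)
        lengths = route_cell_lengths(((0.0, 0.0), (300.0, 300.0)), g)
        assert lengths == pytest.approx({g.cell_id(0, 0): 300 * math.sqrt(2)})

    def test_shared_edge_goes_to_lexicographically_smaller_cell(self):
        g = generate_grid(2, 2, 300)
        # along the horizontal boundary y=300 between rows 0 and 1
        lengths = route_cell_lengths(((0.0, 300.0), (600.0, 300.0)), g)
        assert set(lengths) == {g.cell_id(0, 0), g.cell_id(0, 1)}
        assert sum(lengths.values()) == pytest.approx(600.0)
        # along the vertical boundary x=300 between cols 0 and 1
        lengths = route_cell_lengths(((300.0, 0.0), (300.0, 600.0)), g)
        assert set(lengths) == {g.cell_id(0, 0), g.cell_id(1, 0)}
        assert sum(lengths.values()) == pytest.approx(600.0)

    def test_route_outside_envelope_rejected(self):
        g = generate_grid(2, 2, 300)
        with pytest.raises(DataError, match="envelope"):
            route_cell_lengths(((0.0, 0.0), (700.0, 0.0)), g)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 900), st.floats(0, 600)),
                    min_size=2, max_size=8))
    def test_conservation_for_arbitrary_polylines(self, vertices):
        """Sum of per-cell lengths equals the polyline length (rel tol 1e-9)."""
        g = generate_grid(2, 3, 300)
        coords = np.asarray(vertices)
        total = float(np.hypot(*(coords[1:] - coords[:-1]).T).sum())
        lengths = route_cell_lengths(tuple(vertices), g)
        assert sum(lengths.values()) == pytest.approx(total, rel=1e-9, abs=1e-9)

    def test_matches_fine_sampling_oracle(self, small_city):
        """Per-cell lengths agree with brute-force 0.1 m point sampling."""
        g = small_city.grid
        for route in small_city.routes[:5]:
            lengths = route_cell_lengths(route, g)
            binned = _sampled_lengths(route, g, step=0.1)
            for cid in set(lengths) | set(binned):
                assert lengths.get(cid, 0.0) == pytest.approx(
                    binned.get(cid, 0.0), abs=1.0)


def _sampled_lengths(route, grid, step=0.1):
    """Independent oracle: walk the polyline in tiny steps, bin by cell."""
    out = {}
    coords = np.asarray(route.coords)
    for p0, p1 in zip(coords[:-1], coords[1:]):
        seglen = float(np.hypot(*(p1 - p0)))
        n = max(int(seglen / step), 1)
        ts = (np.arange(n) + 0.5) / n
        pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
        cols = np.minimum((pts[:, 0] // grid.cell_size).astype(int), grid.ncols - 1)
        rows = np.minimum((pts[:, 1] // grid.cell_size).astype(int), grid.nrows - 1)
        for r, c in zip(rows, cols):
            cid = int(r) * grid.ncols + int(c)
            out[cid] = out.get(cid, 0.0) + seglen / n
    return out


class TestCellBusVmt:
    def _one_route_setup(self):
        g = generate_grid(2, 2, 300)
        sched = ServiceSchedule("R1", 2009, 10, 5)  # 3130 buses/yr at 261/104
        route = Route("R1", ((0.0, 150.0), (300.0, 150.0)), ("D0",),
                      schedules={2009: sched})
        rosters = {("D0", 2009): roster("D0", hybrid_2010=25, diesel_2001=75)}
        return g, route, rosters

    def test_single_route_arithmetic(self):
        g, route, rosters = self._one_route_setup()
        tab = cell_bus_vmt([route], rosters, g, 2009, definitions=(NARROW,))
        cid = g.cell_id(0, 0)
        assert tab.loc[cid, "total_vmt"] == pytest.approx(300 * 3130)
        assert tab.loc[cid, "clean_vmt_narrow"] == pytest.approx(300 * 3130 * 0.25)

    def test_additivity_over_routes(self):
        g, route, rosters = self._one_route_setup()
        one = cell_bus_vmt([route], rosters, g, 2009)
        route2 = Route("R2", route.coords, route.depot_ids,
                       schedules={2009: ServiceSchedule("R2", 2009, 10, 5)})
        two = cell_bus_vmt([route, route2], rosters, g, 2009)
        np.testing.assert_allclose(two["total_vmt"], 2 * one["total_vmt"])

    def test_untouched_cells_are_zero(self):
        g, route, rosters = self._one_route_setup()
        tab = cell_bus_vmt([route], rosters, g, 2009)
        assert tab.loc[g.cell_id(1, 1), "total_vmt"] == 0.0


class TestDeltaProp:
    @pytest.mark.parametrize("c1,t1,c2,t2,expected,served", [
        (25, 100, 50, 100, 0.25, True),
        (40, 100, 40, 100, 0.0, True),
        (100, 100, 0, 100, -1.0, True),
        (0, 0, 50, 100, 0.0, False),   # no year-1 service
        (0, 100, 0, 0, 0.0, False),    # no year-2 service
    ])
    def test_values(self, c1, t1, c2, t2, expected, served):
        delta, flag = delta_prop_clean(c1, t1, c2, t2)
        assert delta == pytest.approx(expected)
        assert flag is served

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0, 1e9), st.floats(1e-6, 1e9), st.floats(0, 1e9),
           st.floats(1e-6, 1e9))
    def test_bounded_in_unit_interval(self, c1, t1, c2, t2):
        delta, _ = delta_prop_clean(min(c1, t1), t1, min(c2, t2), t2)
        assert -1.0 <= delta <= 1.0


class TestExposureInvariants:
    def test_narrow_never_exceeds_broad(self, small_city):
        e = small_city.exposure
        for y in small_city.config.years:
            assert (e[f"clean_vmt_narrow_{y}"] <= e[f"clean_vmt_broad_{y}"] + 1e-9).all()
            assert (e[f"clean_vmt_broad_{y}"] <= e[f"total_vmt_{y}"] * (1 + 1e-12) + 1e-9).all()

    def test_delta_prop_within_bounds(self, small_city):
        e = small_city.exposure
        for d in ("broad", "narrow"):
            assert e[f"delta_prop_clean_{d}"].between(-1, 1).all()

    def test_unserved_cells_have_zero_shift(self, small_city):
        e = small_city.exposure
        assert (e.loc[~e["served"], "delta_prop_clean_broad"] == 0).all()

    def test_scale_equivariance_in_frequencies(self, small_city):
        """Multiplying every frequency by k scales VMT by k, leaves shifts fixed."""
        from cleanfleet import build_exposure_table

        c = small_city
        k = 3.0
        scaled = []
        for r in c.routes:
            scheds = {y: ServiceSchedule(r.route_id, y, s.weekday_trips_per_day * k,
                                         s.weekend_trips_per_day * k)
                      for y, s in r.schedules.items()}
            scaled.append(Route(r.route_id, r.coords, r.depot_ids, scheds))
        base = c.exposure
        tab = build_exposure_table(scaled, c.rosters, c.grid, c.config.years)
        for y in c.config.years:
            np.testing.assert_allclose(tab[f"total_vmt_{y}"], k * base[f"total_vmt_{y}"])
        np.testing.assert_allclose(tab["delta_prop_clean_broad"],
                                   base["delta_prop_clean_broad"], atol=1e-12)

    def test_clean_substitution_monotonicity(self, small_city):
        """Swapping a year-2 diesel bus for a hybrid never lowers any cell's
        clean VMT or clean shift."""
        from cleanfleet import build_exposure_table

        c = small_city
        y2 = c.config.years[1]
        rosters = dict(c.rosters)
        depot_id = c.routes[0].depot_ids[0]
        old = rosters[(depot_id, y2)]
        counts = dict(old.counts)
        dirty = next((cat for cat in counts
                      if not is_clean(cat, BROAD) and counts[cat] > 0), None)
        assert dirty is not None, "fixture depot has no non-clean year-2 bus"
        counts[dirty] -= 1
        swap = BusCategory("hybrid", 2010)
        counts[swap] = counts.get(swap, 0) + 1
        rosters[(depot_id, y2)] = FleetRoster(depot_id, y2, counts)
        before = c.exposure
        after = build_exposure_table(c.routes, rosters, c.grid, c.config.years)
        for d in ("broad", "narrow"):
            assert (after[f"clean_vmt_{d}_{y2}"]
                    >= before[f"clean_vmt_{d}_{y2}"] - 1e-9).all()
            assert (after[f"delta_prop_clean_{d}"]
                    >= before[f"delta_prop_clean_{d}"] - 1e-12).all()
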