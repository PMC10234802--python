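"""Serialization: GeoJSON geometry, CSV tables, plain-text config, manifests.

A simulated-city bundle directory contains::

    config.txt        key = value copy of the configuration (incl. seed)
    grid.geojson      cell polygons with id/row/col properties
    routes.geojson    route linestrings with depots and schedules
    rosters.csv       depot_id, year, fuel_type, model_year, count
    covariates.csv    cell_id, truck_route, traffic_vmt, bus_stops_approx
    outcomes.csv      cell_id, d_no, d_no2, d_bc
    truth_params.csv  pollutant, parameter, value (the DGP actually used)
    truth_latent.csv  cell_id, u_<pollutant> latent disturbances
    manifest.json     seed, timestamps, package version, sha256 digests
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from . import __version__
from .errors import ConfigError, DataError
from .exposure import BusCategory, FleetRoster, Route, ServiceSchedule, Calendar
from .grid import Grid, generate_grid
from .simulate import CityBundle, DGPParams, SimConfig

BUNDLE_FILES = ("config.txt", "grid.geojson", "routes.geojson", "rosters.csv",
                "covariates.csv", "outcomes.csv", "truth_params.csv", "truth_latent.csv")


# --------------------------------------------------------------------------- #
# config


def config_to_text(config: SimConfig) -> str:
    lines = []
    for f in dataclasses.fields(SimConfig):
        v = getattr(config, f.name)
        if f.name == "calendar":
            v = (v.n_weekdays, v.n_weekend_days)
        elif f.name == "dgp":
            v = {k: (list(p.beta), p.lam, p.sigma) for k, p in config.dgps().items()}
        lines.append(f"{f.name} = {json.dumps(v, default=list)}")
    return "\n".join(lines) + "\n"


def config_from_text(text: str) -> SimConfig:
    kwargs = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"config line {lineno} is not 'key = value': {line!r}")
        key, _, raw = line.partition("=")
        key = key.strip()
        try:
            val = json.loads(raw.strip())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config line {lineno}: bad value for {key}: {exc}") from exc
        kwargs[key] = val
    return config_from_dict(kwargs)


def config_from_dict(kwargs: dict) -> SimConfig:
    valid = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = sorted(set(kwargs) - valid)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    clean = dict(kwargs)
    if "calendar" in clean and clean["calendar"] is not None:
        wd, we = clean["calendar"]
        clean["calendar"] = Calendar(int(wd), int(we))
    if "fuel_shares" in clean:
        clean["fuel_shares"] = tuple((str(f), float(a), float(b))
                                     for f, a, b in clean["fuel_shares"])
    if "dgp" in clean and clean["dgp"] is not None:
        clean["dgp"] = {k: DGPParams(beta=tuple(b), lam=float(l), sigma=float(s))
                        for k, (b, l, s) in clean["dgp"].items()}
    for key in ("routes_per_depot_range", "route_length_range", "weekday_trips_range",
                "weekend_trips_range", "year2_frequency_scale_range", "years",
                "fleet_per_depot_range", "post2007_share", "pre_vintage_range"):
        if key in clean:
            clean[key] = tuple(clean[key])
    try:
        return SimConfig(**clean)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


# --------------------------------------------------------------------------- #
# geometry


def grid_to_geojson(grid: Grid) -> dict:
    feats = [
        {"type": "Feature",
         "geometry": mapping(c.polygon),
         "properties": {"id": c.id, "row": c.row, "col": c.col}}
        for c in grid.cells
    ]
    return {"type": "FeatureCollection",
            "properties": {"nrows": grid.nrows, "ncols": grid.ncols,
                           "cell_size": grid.cell_size},
            "features": feats}


def grid_from_geojson(obj: dict) -> Grid:
    try:
        p = obj["properties"]
        return generate_grid(int(p["nrows"]), int(p["ncols"]), float(p["cell_size"]))
    except (KeyError, TypeError) as exc:
        raise DataError(f"grid GeoJSON lacks nrows/ncols/cell_size metadata: {exc}") from exc


def routes_to_geojson(routes) -> dict:
    feats = []
    for r in routes:
        feats.append({
            "type": "Feature",
            "geometry": mapping(r.geometry),
            "properties": {
                "route_id": r.route_id,
                "depot_ids": list(r.depot_ids),
                "schedules": {str(y): [s.weekday_trips_per_day, s.weekend_trips_per_day]
                              for y, s in r.schedules.items()},
            },
        })
    return {"type": "FeatureCollection", "features": feats}


def routes_from_geojson(obj: dict):
    routes = []
    for feat in obj.get("features", []):
        props = feat.get("properties", {})
        try:
            rid = props["route_id"]
            geom = shape(feat["geometry"])
            schedules = {
                int(y): ServiceSchedule(rid, int(y), float(wd), float(we))
                for y, (wd, we) in props["schedules"].items()
            }
            routes.append(Route(route_id=rid,
                                coords=tuple((x, y) for x, y in geom.coords),
                                depot_ids=tuple(props["depot_ids"]),
                                schedules=schedules))
        except (KeyError, TypeError, ValueError) as exc:
            raise DataError(f"malformed route feature: {exc}") from exc
    return tuple(routes)


# --------------------------------------------------------------------------- #
# tables


def rosters_to_frame(rosters) -> pd.DataFrame:
    rows = [
        {"depot_id": depot_id, "year": year, "fuel_type": cat.fuel_type,
         "model_year": cat.model_year, "count": cnt}
        for (depot_id, year), roster in sorted(rosters.items())
        for cat, cnt in sorted(roster.counts.items(),
                               key=lambda kv: (kv[0].fuel_type, kv[0].model_year))
    ]
    return pd.DataFrame(rows, columns=["depot_id", "year", "fuel_type",
                                       "model_year", "count"])


def rosters_from_frame(df: pd.DataFrame) -> dict:
    required = ["depot_id", "year", "fuel_type", "model_year", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"roster table is missing columns: {missing}")
    rosters: dict = {}
    for (depot_id, year), sub in df.groupby(["depot_id", "year"]):
        counts = {}
        for _, r in sub.iterrows():
            cat = BusCategory(str(r["fuel_type"]), int(r["model_year"]))
            counts[cat] = counts.get(cat, 0) + int(r["count"])
        rosters[(str(depot_id), int(year))] = FleetRoster(str(depot_id), int(year), counts)
    return rosters


def truth_to_frames(truth: dict):
    params = []
    latent = {}
    for pollutant, rec in sorted(truth.items()):
        params.append({"pollutant": pollutant, "parameter": "beta_intercept",
                       "value": rec.beta[0]})
        for term, b in zip(rec.terms, rec.beta[1:]):
            params.append({"pollutant": pollutant, "parameter": f"beta_{term}", "value": b})
        params.append({"pollutant": pollutant, "parameter": "lambda", "value": rec.lam})
        params.append({"pollutant": pollutant, "parameter": "sigma", "value": rec.sigma})
        latent[f"u_{pollutant}"] = rec.latent_u
    lat = pd.DataFrame(latent)
    lat.index.name = "cell_id"
    return pd.DataFrame(params), lat


# --------------------------------------------------------------------------- #
# bundle directory


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir: Path, seed, extra=None):
    out_dir = Path(out_dir)
    files = sorted(p.name for p in out_dir.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package": "cleanfleet",
        "version": __version__,
        "seed": seed,
        "created_unix": time.time(),
        "digests": {name: _sha256(out_dir / name) for name in files},
    }
    if extra:
        manifest.update(extra)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def write_bundle(bundle: CityBundle, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.txt").write_text(config_to_text(bundle.config.with_seed(bundle.seed)))
    (out / "grid.geojson").write_text(json.dumps(grid_to_geojson(bundle.grid)))
    (out / "routes.geojson").write_text(json.dumps(routes_to_geojson(bundle.routes)))
    rosters_to_frame(bundle.rosters).to_csv(out / "rosters.csv", index=False)
    bundle.covariates.to_csv(out / "covariates.csv")
    bundle.outcomes.to_csv(out / "outcomes.csv")
    params, latent = truth_to_frames(bundle.truth)
    params.to_csv(out / "truth_params.csv", index=False)
    latent.to_csv(out / "truth_latent.csv")
    write_manifest(out, bundle.seed)
    return out


def read_bundle(bundle_dir):
    """Load the parts of a bundle that downstream stages consume."""
    d = Path(bundle_dir)
    missing = [f for f in BUNDLE_FILES if not (d / f).exists()]
    if missing:
        raise DataError(f"bundle at {d} is missing files: {missing}")
    config = config_from_text((d / "config.txt").read_text())
    grid = grid_from_geojson(json.loads((d / "grid.geojson").read_text()))
    routes = routes_from_geojson(json.loads((d / "routes.geojson").read_text()))
    rosters = rosters_from_frame(pd.read_csv(d / "rosters.csv"))
    covariates = pd.read_csv(d / "covariates.csv", index_col="cell_id")
    outcomes = pd.read_csv(d / "outcomes.csv", index_col="cell_id")
    return config, grid, routes, rosters, covariates, outcomes
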