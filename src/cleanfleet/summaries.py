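"""Descriptive outputs: fleet composition and the three-group cell table.

The three groups partition all cells by their clean-fleet shift: cells
with no bus service in one or both years; served cells at or below the
median shift (median taken over served cells only, ties going to the lower
group); and served cells above the median.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .exposure import BROAD, NARROW, is_clean

__all__ = ["GROUPS", "dichotomize_clean_shift", "fleet_composition",
           "group_summary", "render_group_table"]

GROUPS = ("no_service", "at_or_below_median", "above_median")


def dichotomize_clean_shift(exposure: pd.DataFrame, definition: str = "broad") -> pd.Series:
    """Assign every cell to one of the three descriptive groups."""
    col = f"delta_prop_clean_{definition}"
    if col not in exposure.columns or "served" not in exposure.columns:
        raise DataError(f"exposure table lacks {col!r} or 'served'")
    served = exposure["served"].to_numpy(dtype=bool)
    if not served.any():
        raise DataError("no served cells: cannot compute a median clean shift")
    vals = exposure[col].to_numpy()
    med = float(np.median(vals[served]))
    out = np.where(~served, GROUPS[0],
                   np.where(vals <= med, GROUPS[1], GROUPS[2]))
    return pd.Series(pd.Categorical(out, categories=list(GROUPS)),
                     index=exposure.index, name="group")


def fleet_composition(rosters) -> pd.DataFrame:
    """Citywide fleet shares per year.

    Rows: one per year; columns: each fuel-type share, the post-cutoff
    vintage share, and the clean share under both definitions.
    """
    years = sorted({year for (_, year) in rosters})
    if len(years) < 2:
        raise DataError(f"rosters must cover both study years, found {years}")
    rows = []
    for year in years:
        counts: dict = {}
        for (depot_id, y), roster in rosters.items():
            if y != year:
                continue
            for cat, cnt in roster.counts.items():
                counts[cat] = counts.get(cat, 0) + cnt
        total = sum(counts.values())
        if total == 0:
            raise DataError(f"no buses rostered in year {year}")
        row = {"year": year, "total_buses": total}
        for fuel in ("diesel", "ULSD", "CNG", "hybrid"):
            row[f"share_{fuel}"] = sum(c for k, c in counts.items()
                                       if k.fuel_type == fuel) / total
        cutoff = BROAD.vintage_cutoff
        row[f"share_post{cutoff}"] = sum(c for k, c in counts.items()
                                         if k.model_year >= cutoff) / total
        for d in (BROAD, NARROW):
            row[f"share_clean_{d.name}"] = sum(c for k, c in counts.items()
                                               if is_clean(k, d)) / total
        rows.append(row)
    return pd.DataFrame(rows).set_index("year")


# columns summarized per group: (output name, source column, as_percent)
def _summary_columns(exposure, covariates, outcomes, years, definition):
    y1, y2 = years
    d = definition
    tab = pd.DataFrame(index=exposure.index)
    spec = []
    tab["delta_prop_clean"] = exposure[f"delta_prop_clean_{d}"] * 100.0
    spec.append(("delta_prop_clean_pct", "mean_sd"))
    for label, col in ((f"clean_vmt_{y1}_km", f"clean_vmt_{d}_{y1}"),
                       (f"clean_vmt_{y2}_km", f"clean_vmt_{d}_{y2}"),
                       (f"total_vmt_{y1}_km", f"total_vmt_{y1}"),
                       (f"total_vmt_{y2}_km", f"total_vmt_{y2}")):
        tab[label] = exposure[col] / 1000.0  # stored meters -> reported km
        spec.append((label, "mean_sd"))
    tab["bus_stops_approx"] = covariates["bus_stops_approx"]
    spec.append(("bus_stops_approx", "mean_sd"))
    tab["truck_route"] = covariates["truck_route"] * 100.0
    spec.append(("truck_route_pct", "prevalence"))
    tab["traffic_vmt"] = covariates["traffic_vmt"]
    spec.append(("traffic_vmt", "mean_sd"))
    for col in outcomes.columns:
        tab[col] = outcomes[col]
        spec.append((col, "mean_sd"))
    tab.columns = [name for name, _ in spec]
    return tab, spec


def group_summary(assignments: pd.Series, exposure: pd.DataFrame,
                  covariates: pd.DataFrame, outcomes: pd.DataFrame,
                  years, definition: str = "broad") -> pd.DataFrame:
    """Three-group descriptive table: n, mean, and sample SD per variable.

    SDs use the n-1 denominator; a single-cell group reports a blank (NaN)
    SD; an empty group reports n=0 with blank statistics. VMT is converted
    to km and proportions to percentages for reporting.
    """
    if len(assignments) != len(exposure):
        raise DataError("group assignments do not cover every cell")
    tab, spec = _summary_columns(exposure, covariates, outcomes, years, definition)
    rows = []
    for group in GROUPS:
        mask = (assignments == group).to_numpy()
        n = int(mask.sum())
        row = {"group": group, "n": n}
        for name, _kind in spec:
            vals = tab.loc[mask, name].to_numpy(dtype=float)
            row[f"{name}_mean"] = float(vals.mean()) if n > 0 else np.nan
            row[f"{name}_sd"] = float(vals.std(ddof=1)) if n > 1 else np.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("group")
    assert int(out["n"].sum()) == len(exposure)
    return out


def render_group_table(summary: pd.DataFrame) -> str:
    """Plain-text rendering of the group table, percentages to 2 decimals."""
    lines = [f"{'variable':<28}" + "".join(f"{g:>26}" for g in summary.index)]
    lines.append(f"{'n':<28}" + "".join(f"{int(summary.loc[g, 'n']):>26d}"
                                        for g in summary.index))
    variables = sorted({c[:-5] for c in summary.columns if c.endswith("_mean")})
    for var in variables:
        cells = []
        for g in summary.index:
            m = summary.loc[g, f"{var}_mean"]
            s = summary.loc[g, f"{var}_sd"]
            if np.isnan(m):
                cells.append(f"{'—':>26}")
            elif var.endswith("_pct"):
                cells.append(f"{m:>17.2f}% ({s:6.2f})" if not np.isnan(s)
                             else f"{m:>19.2f}% (   )")
            else:
                cells.append(f"{m:>14.4g} ({s:9.4g})" if not np.isnan(s)
                             else f"{m:>14.4g} (      )")
        lines.append(f"{var:<28}" + "".join(cells))
    return "\n".join(lines)
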