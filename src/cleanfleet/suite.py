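"""Regression suite: Models 1-3 per pollutant and clean definition.

Model 1 regresses the pollutant-concentration change on the clean-shift
statistic alone; Model 2 adds the confounders (log total traffic, truck
route); Model 3 further adds log baseline bus VMT. Traffic and bus VMT are
log(x + 1)-transformed in their stored unit (meters for bus VMT) because
both are strongly right-skewed and contain zeros; the offset and unit are
part of the output metadata since coefficient scale depends on them.

By default all grid cells enter the regression, with a clean shift of 0
and zero bus VMT for unserved cells; ``sample='served_only'`` restricts to
cells served in both years (the contiguity weights are subset and
re-standardized accordingly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CleanFleetError, DataError
from .sem import SpatialErrorModel
from .weights import SpatialWeights

__all__ = ["MODEL_TERMS", "ModelSpec", "build_analysis_table", "fit_model_suite"]

MODEL_TERMS = {
    1: ["delta_prop_clean"],
    2: ["delta_prop_clean", "log_traffic", "truck_route"],
    3: ["delta_prop_clean", "log_traffic", "truck_route", "log_bus_vmt_2009"],
}

POLLUTANTS = ("d_no", "d_no2", "d_bc")
LOG_OFFSET = 1.0


@dataclass(frozen=True)
class ModelSpec:
    """One regression: outcome pollutant, model number, clean definition."""

    outcome: str
    model: int
    definition: str = "broad"

    def __post_init__(self):
        if self.model not in MODEL_TERMS:
            raise DataError(f"model must be one of {sorted(MODEL_TERMS)}, got {self.model}")
        if self.definition not in ("broad", "narrow"):
            raise DataError(f"definition must be 'broad' or 'narrow', got {self.definition!r}")

    @property
    def terms(self):
        return list(MODEL_TERMS[self.model])


def build_analysis_table(exposure: pd.DataFrame, covariates: pd.DataFrame,
                         outcomes: pd.DataFrame, years, definition: str = "broad",
                         log_offset: float = LOG_OFFSET) -> pd.DataFrame:
    """Join exposure, covariates, and outcomes into one modeling table.

    Indexes must agree cell-for-cell; mismatches are reported with counts.
    """
    for name, df in (("covariates", covariates), ("outcomes", outcomes)):
        if not exposure.index.equals(df.index):
            common = exposure.index.intersection(df.index)
            raise DataError(
                f"exposure and {name} tables do not align: {len(exposure)} vs "
                f"{len(df)} rows, {len(common)} shared cell ids")
    y1 = years[0]
    tab = pd.DataFrame(index=exposure.index)
    tab["delta_prop_clean"] = exposure[f"delta_prop_clean_{definition}"]
    tab["log_traffic"] = np.log(covariates["traffic_vmt"] + log_offset)
    tab["truck_route"] = covariates["truck_route"].astype(float)
    tab["log_bus_vmt_2009"] = np.log(exposure[f"total_vmt_{y1}"] + log_offset)
    tab["served"] = exposure["served"]
    for col in outcomes.columns:
        tab[col] = outcomes[col]
    return tab


def fit_model_suite(analysis: pd.DataFrame, weights: SpatialWeights,
                    pollutants=POLLUTANTS, models=(1, 2, 3),
                    definition: str = "broad",
                    sample: str = "all_cells") -> pd.DataFrame:
    """Fit every requested (pollutant, model) spatial error model.

    Returns a long coefficients table with one row per term per fit:
    columns model, pollutant, definition, sample, term, estimate, se,
    ci_low, ci_high, pvalue, significant, lambda, loglik, n. A fit that
    fails is recorded as a row with an ``error`` message; the rest of the
    suite still runs.
    """
    if sample not in ("all_cells", "served_only"):
        raise DataError(f"sample must be 'all_cells' or 'served_only', got {sample!r}")
    if sample == "served_only":
        keep = np.flatnonzero(analysis["served"].to_numpy())
        analysis = analysis.iloc[keep]
        weights = weights.subset(keep)
    rows = []
    for pollutant in pollutants:
        for m in models:
            spec = ModelSpec(pollutant, m, definition)
            base = {"model": m, "pollutant": pollutant, "definition": definition,
                    "sample": sample}
            try:
                model = SpatialErrorModel.from_dataframe(
                    analysis, pollutant, spec.terms, weights)
                res = model.fit()
            except CleanFleetError as exc:
                rows.append({**base, "term": None, "error": str(exc)})
                continue
            frame = res.to_frame()
            for _, r in frame.iterrows():
                rows.append({**base, "term": r["term"], "estimate": r["estimate"],
                             "se": r["se"], "ci_low": r["ci_low"],
                             "ci_high": r["ci_high"], "pvalue": r["pvalue"],
                             "significant": bool(r["significant"]),
                             "lambda": res.lam, "loglik": res.llf,
                             "n": res.nobs, "error": None})
    return pd.DataFrame(rows)
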