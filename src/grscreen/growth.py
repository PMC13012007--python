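"""Growth metrics: relative total area, normalized area, GR values.

The per-well growth-rate proxy is the *relative total area*: tumoroid-covered
area on the readout day divided by the same well's day-1 area.  The GR
(growth-rate inhibition) value normalizes a treated well's growth to the mean
growth of the sample's vehicle controls on a log2 scale:

    GR = 2**(log2(g_condition) / log2(g_control)) - 1

so GR = 1 means growth identical to control, GR = 0 complete cytostasis
(no net growth) and GR < 0 net area loss (cytotoxicity).  The uncorrected
comparison readout is the *normalized relative total area*: condition
relative area divided by mean vehicle relative area.

GR values are computed per technical replicate and then averaged — never the
GR of the replicate-mean growth rate, which would be biased by Jensen's
inequality.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .design import VEHICLE_LABEL

__all__ = [
    "relative_total_area",
    "gr_value",
    "per_sample_gr",
    "normalized_relative_area",
    "compute_growth_table",
    "aggregate_conditions",
    "is_successful",
    "success_rate",
    "SUCCESS_THRESHOLD",
]

#: Minimum mean vehicle-control relative total area on day 7 for a culture
#: to count as successful.
SUCCESS_THRESHOLD = 1.2


def relative_total_area(areas: dict | pd.Series, day: int) -> float:
    """Area on ``day`` divided by the same well's day-1 area.

    ``areas`` maps imaging day to tumoroid-covered area.  Missing readout
    day returns NaN (flagged by the caller); a missing or non-positive
    baseline is an error because every downstream metric divides by it.
    """
    if 1 not in areas:
        raise ValueError("well has no day-1 baseline area")
    baseline = areas[1]
    if not np.isfinite(baseline) or baseline <= 0:
        raise ValueError(f"day-1 baseline must be positive, got {baseline}")
    if day not in areas or not np.isfinite(areas[day]):
        return float("nan")
    return float(areas[day] / baseline)


def gr_value(growth_rate_condition: float, growth_rate_control: float) -> float:
    """GR value of one replicate: 2**(log2(condition)/log2(control)) - 1."""
    if growth_rate_condition <= 0 or growth_rate_control <= 0:
        raise ValueError("growth rates must be positive")
    log_ctrl = np.log2(growth_rate_control)
    if log_ctrl == 0.0:
        raise ValueError(
            "control growth rate of exactly 1 (zero net growth) leaves GR undefined"
        )
    return float(2.0 ** (np.log2(growth_rate_condition) / log_ctrl) - 1.0)


def per_sample_gr(gr_values) -> tuple[float, float, int]:
    """Mean of per-replicate GR values with dispersion.

    Returns (mean, sd, n).  The mean is taken over replicate-level GR values
    (Jensen guard: NOT the GR of the mean growth rate).  With a single
    replicate the sd is NaN.
    """
    vals = np.asarray([v for v in gr_values if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("no valid replicate GR values")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
    return float(vals.mean()), sd, int(vals.size)


def normalized_relative_area(condition_rel_areas, vehicle_rel_areas) -> float:
    """Replicate-mean of condition relative areas over the vehicle mean."""
    veh = np.asarray(list(vehicle_rel_areas), dtype=float)
    veh = veh[np.isfinite(veh)]
    if veh.size == 0 or veh.mean() <= 0:
        raise ValueError("vehicle mean relative area must be positive")
    cond = np.asarray(list(condition_rel_areas), dtype=float)
    cond = cond[np.isfinite(cond)]
    if cond.size == 0:
        raise ValueError("no valid condition relative areas")
    return float((cond / veh.mean()).mean())


def compute_growth_table(
    areas: pd.DataFrame,
    readout_day: int = 7,
    *,
    vehicle_label: str = VEHICLE_LABEL,
    epsilon: float = 1e-3,
) -> pd.DataFrame:
    """Per-well growth metrics at the readout day.

    Input is the shared long-format area table (sample_id, drug,
    concentration, unit, replicate, day, area).  Output has one row per well
    with columns ``relative_total_area``, ``normalized_relative_area``,
    ``gr_value``, ``control_mean_rel_area``, ``successful`` and a ``flag``
    column recording exclusions and floors.

    Vehicle normalization pools all of a sample's vehicle wells at the
    readout day.  Wells missing the readout day are flagged and excluded
    from control means rather than imputed.  A measured relative area <=
    ``epsilon`` is floored to ``epsilon`` (GR needs positive growth rates)
    and flagged.
    """
    required = {"sample_id", "drug", "concentration", "replicate", "day", "area"}
    missing = required - set(areas.columns)
    if missing:
        raise ValueError(f"area table missing columns: {sorted(missing)}")

    records = []
    well_keys = ["sample_id", "drug", "concentration", "replicate"]
    for key, well in areas.groupby(well_keys, sort=False):
        day_area = dict(zip(well["day"], well["area"]))
        flag = ""
        rel = relative_total_area(day_area, readout_day)
        if np.isnan(rel):
            flag = "missing_readout_day"
        elif rel <= epsilon:
            rel, flag = epsilon, "floored_to_epsilon"
        rec = dict(zip(well_keys, key))
        rec.update(
            unit=well["unit"].iloc[0] if "unit" in well else "",
            day=readout_day,
            relative_total_area=rel,
            flag=flag,
        )
        records.append(rec)
    out = pd.DataFrame(records)

    n_excluded = int((out["flag"] == "missing_readout_day").sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} wells missing day {readout_day}; excluded from means")

    is_vehicle = out["drug"] == vehicle_label
    ctrl_mean = (
        out[is_vehicle].groupby("sample_id")["relative_total_area"].mean().rename("control_mean_rel_area")
    )
    out = out.merge(ctrl_mean, on="sample_id", how="left", validate="many_to_one")
    if out["control_mean_rel_area"].isna().any():
        bad = out.loc[out["control_mean_rel_area"].isna(), "sample_id"].unique()
        raise ValueError(f"samples without vehicle wells: {list(bad)}")

    out["normalized_relative_area"] = out["relative_total_area"] / out["control_mean_rel_area"]

    def _gr(row):
        if not np.isfinite(row["relative_total_area"]):
            return np.nan
        if row["control_mean_rel_area"] == 1.0:
            return np.nan  # zero net control growth; sample fails success criterion anyway
        return gr_value(row["relative_total_area"], row["control_mean_rel_area"])

    out["gr_value"] = out.apply(_gr, axis=1)
    out["successful"] = out["control_mean_rel_area"] >= SUCCESS_THRESHOLD
    return out


def aggregate_conditions(growth: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean GR and normalized area per sample–drug–concentration."""
    rows = []
    for key, grp in growth.groupby(["sample_id", "drug", "concentration"], sort=True):
        mean_gr, sd_gr, n = per_sample_gr(grp["gr_value"])
        rows.append(
            {
                "sample_id": key[0],
                "drug": key[1],
                "concentration": key[2],
                "gr_mean": mean_gr,
                "gr_sd": sd_gr,
                "normalized_area_mean": float(grp["normalized_relative_area"].mean()),
                "n_replicates": n,
            }
        )
    return pd.DataFrame(rows)


def is_successful(
    vehicle_rel_areas,
    threshold: float = SUCCESS_THRESHOLD,
) -> bool:
    """Culture-success criterion: mean vehicle relative total area on day 7
    of at least ``threshold`` (boundary included)."""
    vals = np.asarray(list(vehicle_rel_areas), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no vehicle day-7 relative areas available")
    return bool(vals.mean() >= threshold)


def success_rate(n_successful: int, n_sampled: int, n_experimental_errors: int = 0) -> float:
    """Culture success rate in percent, excluding experimental errors from
    the denominator: 100 * n_successful / (n_sampled - n_errors)."""
    denom = n_sampled - n_experimental_errors
    if denom <= 0 or n_successful < 0 or n_successful > denom:
        raise ValueError("inconsistent sample counts")
    return 100.0 * n_successful / denom
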