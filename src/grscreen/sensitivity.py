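"""Drug-sensitivity readouts and classifiers.

From each fitted dose–response curve this module extracts:

* GR50 / ED20 by the *absolute* method — the concentration at which the
  inferred GR value equals 0.5 (GR50) or the inferred normalized relative
  total area equals 0.8 (ED20, i.e. 20% inhibition).  Found by root-finding
  on the analytic fitted curve, not by grid lookup; a curve whose lower
  asymptote stays above the level within the tested range is NOT_REACHED
  (recorded as NaN with a ``reached`` flag).
* AOC (area over the curve) — the trapezoidal integral of (1 - response)
  over the 1,000-point inferred grid.  Higher AOC = more sensitive; unlike
  GR50 it exists for every fitted sample and integrates the whole range.

Samples are called sensitive or resistant against the library median of each
readout, and precision of the library medians is quantified by a percentile
bootstrap.  When both drugs are screened, treatment is allocated by AOC
(GR50 as supporting evidence only): the drug with the larger relative
distance above the median, or — if the sample is resistant to both — the
drug closest below its median.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import linregress, pearsonr

from .dose_response import DoseResponseFit, InferredCurve, fit_library, infer_curve

__all__ = [
    "GR50_LEVEL",
    "ED20_LEVEL",
    "absolute_ed",
    "aoc",
    "classify",
    "allocate_treatment",
    "summarize_library",
    "gr50_aoc_correlation",
    "sensitivity_profiles",
    "add_library_calls",
    "format_report",
]

GR50_LEVEL = 0.5
ED20_LEVEL = 0.8


def absolute_ed(
    fit: DoseResponseFit,
    level: float,
    c_min: float | None = None,
    c_max: float | None = None,
) -> float:
    """Smallest tested concentration at which the inferred response equals
    ``level`` (absolute method).

    The fitted LL.3u curve is monotone decreasing, so the crossing is unique;
    it is located by bisection (Brent) on the analytic curve.  Returns NaN
    (NOT_REACHED) when the curve never descends to ``level`` within
    [c_min, c_max]; returns c_min when the response is already at or below
    the level at the lowest tested concentration (crossing below range,
    clamped into it).
    """
    if not fit.converged:
        raise ValueError(f"cannot extract ED from a non-converged fit: {fit.message}")
    c_min = fit.c_min if c_min is None else c_min
    c_max = fit.c_max if c_max is None else c_max
    f_lo = fit.predict(c_min) - level
    f_hi = fit.predict(c_max) - level
    if f_hi > 0:
        return float("nan")  # NOT_REACHED within the tested range
    if f_lo <= 0:
        return float(c_min)
    return float(brentq(lambda c: fit.predict(c) - level, c_min, c_max, xtol=1e-12, rtol=1e-15))


def aoc(curve: InferredCurve | tuple) -> float:
    """Area over the curve: trapezoidal integral of (1 - response).

    AOC = sum_i (x_{i+1} - x_i) * ((1 - y_i) + (1 - y_{i+1})) / 2 over the
    ordered concentration grid.  Bounded by 2 x (c_max - c_min) because the
    GR response is bounded below by -1.
    """
    if isinstance(curve, InferredCurve):
        x, y = curve.concentrations, curve.responses
    else:
        x, y = (np.asarray(v, dtype=float) for v in curve)
    if len(x) < 2:
        raise ValueError("need at least two grid points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("concentration grid must be strictly increasing")
    return float(np.trapezoid(1.0 - y, x))


def classify(value: float, library_median: float, kind: str) -> str:
    """Sensitive/resistant call against the library median.

    GR50/ED20: lower concentration than the median means more sensitive;
    NOT_REACHED (NaN) is resistant.  AOC: larger than the median means more
    sensitive.  Values exactly equal to the median classify as resistant.
    """
    if kind in ("gr50", "ed20"):
        if not np.isfinite(value):
            return "resistant"
        return "sensitive" if value < library_median else "resistant"
    if kind == "aoc":
        return "sensitive" if value > library_median else "resistant"
    raise ValueError(f"unknown readout kind: {kind!r}")


def allocate_treatment(
    aocs: dict[str, float],
    aoc_medians: dict[str, float],
    gr50_calls: dict[str, str] | None = None,
) -> dict:
    """Recommend one of two drugs for a sample from its AOC profile.

    AOC is the primary classifier.  Discordant calls: the AOC-sensitive drug.
    Both sensitive: the drug with the largest relative distance above its
    library median, (AOC - median)/median.  Both resistant: the drug with the
    smallest relative distance below its median.  GR50 concordance, when
    supplied, is reported as supporting evidence and never overrides AOC.
    """
    drugs = sorted(aocs)
    if len(drugs) != 2 or set(aoc_medians) < set(drugs):
        raise ValueError("need AOC values and medians for exactly two drugs")
    for d in drugs:
        if not np.isfinite(aocs[d]):
            raise ValueError(f"missing AOC for {d}")
    dist = {d: (aocs[d] - aoc_medians[d]) / aoc_medians[d] for d in drugs}
    call = {d: classify(aocs[d], aoc_medians[d], "aoc") for d in drugs}
    sensitive = [d for d in drugs if call[d] == "sensitive"]
    if len(sensitive) == 1:
        choice, rule = sensitive[0], "discordant AOC calls: allocate the AOC-sensitive drug"
    elif len(sensitive) == 2:
        choice = max(drugs, key=lambda d: dist[d])
        rule = "sensitive to both: largest relative distance above the median AOC"
    else:
        choice = max(drugs, key=lambda d: dist[d])
        rule = "resistant to both: smallest relative distance below the median AOC"
    result = {
        "recommended_drug": choice,
        "rule": rule,
        "aoc_calls": call,
        "relative_distance": dist,
    }
    if gr50_calls is not None:
        result["gr50_supports"] = gr50_calls.get(choice) == "sensitive"
        result["gr50_calls"] = dict(gr50_calls)
    return result


def summarize_library(
    values,
    *,
    n_boot: int = 5000,
    seed: int = 20260304,
    ci_level: float = 0.95,
) -> dict:
    """Median with IQR, unscaled MAD and a percentile-bootstrap CI.

    IQR quartiles use linear interpolation; the MAD is median |x - median|
    without the 1.4826 normal-consistency factor.  The bootstrap resamples
    samples with replacement (``n_boot`` resamples, fixed seed) and takes
    percentiles of the resampled medians.
    """
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 values to summarize")
    med = float(np.median(vals))
    q1, q3 = (float(q) for q in np.percentile(vals, [25, 75]))
    mad = float(np.median(np.abs(vals - med)))
    rng = np.random.default_rng(seed)
    boot = np.median(rng.choice(vals, size=(n_boot, vals.size), replace=True), axis=1)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(boot, [100 * alpha, 100 * (1 - alpha)])
    return {
        "median": med,
        "iqr": (q1, q3),
        "mad_unscaled": mad,
        "ci": (float(lo), float(hi)),
        "ci_level": ci_level,
        "n": int(vals.size),
        "n_boot": n_boot,
        "boot_seed": seed,
    }


def gr50_aoc_correlation(gr50, aoc_values) -> dict:
    """Pearson correlation and linear regression of log2(GR50) on AOC.

    Samples whose GR50 was not reached (NaN) are excluded and counted.
    Zero AOC variance leaves the correlation undefined (NaN, flagged).
    """
    g = np.asarray(list(gr50), dtype=float)
    a = np.asarray(list(aoc_values), dtype=float)
    if g.shape != a.shape:
        raise ValueError("gr50 and aoc must have equal length")
    ok = np.isfinite(g) & np.isfinite(a) & (g > 0)
    n_excluded = int((~ok).sum())
    g, a = g[ok], a[ok]
    if g.size < 3:
        raise ValueError("need >= 3 samples with reached GR50")
    logg = np.log2(g)
    if np.std(a) == 0 or np.std(logg) == 0:
        warnings.warn("zero variance: correlation undefined")
        return {"r": float("nan"), "p_value": float("nan"), "slope": float("nan"),
                "intercept": float("nan"), "n": int(g.size), "n_excluded": n_excluded,
                "flag": "zero_variance"}
    r, p = pearsonr(logg, a)
    reg = linregress(a, logg)  # log2(GR50) as a function of AOC
    return {
        "r": float(r),
        "p_value": float(p),
        "slope": float(reg.slope),
        "intercept": float(reg.intercept),
        "n": int(g.size),
        "n_excluded": n_excluded,
        "flag": "",
    }


def sensitivity_profiles(
    gr_fits: list[DoseResponseFit],
    area_fits: list[DoseResponseFit] | None = None,
) -> pd.DataFrame:
    """Per sample–drug profile: GR50 and AOC from the GR lane, ED20 from the
    normalized-area lane (when supplied).  Non-converged fits yield NaN rows
    flagged in ``fit_ok``."""
    area_by_key = {}
    if area_fits is not None:
        area_by_key = {(f.sample_id, f.drug): f for f in area_fits}
    rows = []
    for f in gr_fits:
        row = {"sample_id": f.sample_id, "drug": f.drug, "fit_ok": f.converged,
               "gr50": np.nan, "gr50_reached": False, "aoc": np.nan,
               "ed20": np.nan, "ed20_reached": False}
        if f.converged:
            gr50 = absolute_ed(f, GR50_LEVEL)
            row["gr50"] = gr50
            row["gr50_reached"] = bool(np.isfinite(gr50))
            row["aoc"] = aoc(infer_curve(f))
        af = area_by_key.get((f.sample_id, f.drug))
        if af is not None and af.converged:
            ed20 = absolute_ed(af, ED20_LEVEL)
            row["ed20"] = ed20
            row["ed20_reached"] = bool(np.isfinite(ed20))
        rows.append(row)
    return pd.DataFrame(rows)


def add_library_calls(profiles: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Append sensitive/resistant calls against per-drug library medians.

    GR50 medians are computed over reached values only (NOT_REACHED samples
    are excluded from the median but classified resistant); AOC medians over
    all fitted samples.  Returns the augmented table and the cutoffs.
    """
    profiles = profiles.copy()
    cutoffs: dict[str, dict[str, float]] = {}
    for drug, grp in profiles.groupby("drug"):
        med_gr50 = float(np.nanmedian(grp.loc[grp["gr50_reached"], "gr50"])) if grp["gr50_reached"].any() else float("nan")
        med_aoc = float(np.nanmedian(grp["aoc"]))
        cutoffs[drug] = {"median_gr50": med_gr50, "median_aoc": med_aoc}
        idx = grp.index
        profiles.loc[idx, "call_gr50"] = [
            classify(v, med_gr50, "gr50") if np.isfinite(med_gr50) else "NA"
            for v in grp["gr50"]
        ]
        profiles.loc[idx, "call_aoc"] = [classify(v, med_aoc, "aoc") for v in grp["aoc"]]
        if grp["ed20"].notna().any():
            med_ed20 = float(np.nanmedian(grp.loc[grp["ed20_reached"], "ed20"]))
            cutoffs[drug]["median_ed20"] = med_ed20
            profiles.loc[idx, "call_ed20"] = [classify(v, med_ed20, "ed20") for v in grp["ed20"]]
    return profiles, cutoffs


def format_report(sample_id: str, profiles: pd.DataFrame, cutoffs: dict) -> str:
    """Human-readable drug-sensitivity report for one sample."""
    sub = profiles[profiles["sample_id"] == sample_id]
    if sub.empty:
        raise KeyError(sample_id)
    lines = [f"Drug sensitivity report — sample {sample_id}", "=" * 46]
    for _, row in sub.iterrows():
        drug = row["drug"]
        gr50 = f"{row['gr50']:.3g}" if row["gr50_reached"] else "not reached"
        lines += [
            f"{drug}:",
            f"  GR50: {gr50} (library median {cutoffs[drug]['median_gr50']:.3g})"
            f" -> {row.get('call_gr50', 'NA')}",
            f"  AOC:  {row['aoc']:.4g} (library median {cutoffs[drug]['median_aoc']:.4g})"
            f" -> {row.get('call_aoc', 'NA')}",
        ]
    if len(sub) == 2 and sub["aoc"].notna().all():
        alloc = allocate_treatment(
            dict(zip(sub["drug"], sub["aoc"])),
            {d: cutoffs[d]["median_aoc"] for d in sub["drug"]},
            gr50_calls=dict(zip(sub["drug"], sub.get("call_gr50", ["NA"] * 2))),
        )
        lines += [f"Recommended agent: {alloc['recommended_drug']}  ({alloc['rule']})"]
    return "\n".join(lines)
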