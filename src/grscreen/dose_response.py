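"""Three-parameter log-logistic dose–response fitting (upper asymptote = 1).

The response model is

    f(c) = GR_inf + (1 - GR_inf) / (1 + (c / GEC50)**h)

where GR_inf is the lower asymptote, GEC50 the concentration of half-maximal
observed effect and h a Hill-type slope.  The same model is fitted to two
response lanes: growth-rate-corrected GR values and uncorrected normalized
relative total area ("viability-style").  Fitted curves are evaluated on a
1,000-point grid uniform in linear concentration over the tested range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ll3u",
    "DoseResponseFit",
    "InferredCurve",
    "predict",
    "fit_ll3u",
    "fit_library",
    "infer_curve",
    "library_mean_curve",
]

N_CURVE_POINTS = 1000


def ll3u(c, gr_inf: float, gec50: float, h: float):
    """Log-logistic response with the upper limit fixed at 1.

    Accepts scalar or array concentrations; c = 0 maps exactly to 1.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    out = gr_inf + (1.0 - gr_inf) / (1.0 + (c / gec50) ** h)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted LL.3u parameters for one sample–drug–readout combination."""

    sample_id: str
    drug: str
    response: str  # "gr" or "area"
    gr_inf: float
    gec50: float
    h: float
    rse: float
    converged: bool
    n_points: int
    c_min: float
    c_max: float
    message: str = ""

    def predict(self, c):
        if not self.converged:
            raise ValueError(f"fit did not converge: {self.message}")
        return ll3u(c, self.gr_inf, self.gec50, self.h)


@dataclass(frozen=True)
class InferredCurve:
    """Responses evaluated on a uniform (linear) concentration grid."""

    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.responses):
            raise ValueError("grid and responses differ in length")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentration grid must be strictly increasing")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")


def predict(fit: DoseResponseFit, c):
    """Inferred response at concentration(s) ``c``; predict(fit, GEC50) = (1+GR_inf)/2."""
    return fit.predict(c)


def _failed(sample_id, drug, response, n, c_min, c_max, message) -> DoseResponseFit:
    return DoseResponseFit(
        sample_id=sample_id, drug=drug, response=response,
        gr_inf=np.nan, gec50=np.nan, h=np.nan, rse=np.nan,
        converged=False, n_points=n, c_min=c_min, c_max=c_max, message=message,
    )


def fit_ll3u(
    concentrations,
    responses,
    *,
    weights=None,
    sample_id: str = "",
    drug: str = "",
    response: str = "gr",
    flat_tol: float = 1e-6,
) -> DoseResponseFit:
    """Least-squares LL.3u fit with the upper asymptote pinned at 1.

    GEC50 is optimized on the log10 scale for stability; starting values are
    GR_inf = min response, GEC50 = geometric mid-range, h = 1, with a small
    grid of alternative slope starts to escape poor local minima.  Bounds:
    GR_inf in [-1, 1], h in (0, 10].  Requires responses at >= 3 distinct
    concentrations.  A flat response profile (all values ~1, no dose effect)
    or optimizer failure yields a flagged non-fit rather than an exception.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    ok = np.isfinite(c) & np.isfinite(y)
    c, y = c[ok], y[ok]
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float)[ok])
    else:
        w = np.ones_like(y)
    distinct = np.unique(c[c > 0])
    if distinct.size < 3:
        raise ValueError("need responses at >= 3 distinct positive concentrations")
    c_min, c_max = float(distinct[0]), float(distinct[-1])
    n = int(y.size)

    if np.all(np.abs(y - 1.0) < flat_tol) or np.std(y) < flat_tol:
        return _failed(sample_id, drug, response, n, c_min, c_max, "flat response, no dose effect")

    lo = np.array([-1.0, np.log10(c_min) - 3.0, 1e-3])
    hi = np.array([1.0, np.log10(c_max) + 3.0, 10.0])

    def resid(theta):
        gr_inf, log_gec50, h = theta
        return w * (ll3u(c, gr_inf, 10.0**log_gec50, h) - y)

    gr_inf0 = float(np.clip(np.min(y), -0.999, 0.999))
    log_mid = 0.5 * (np.log10(c_min) + np.log10(c_max))
    best = None
    for h0 in (1.0, 0.5, 2.0, 4.0):
        x0 = np.clip(np.array([gr_inf0, log_mid, h0]), lo, hi)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:  # pragma: no cover - trf is robust within bounds
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return _failed(sample_id, drug, response, n, c_min, c_max, "optimizer failure")

    gr_inf, log_gec50, h = best.x
    ssr = float(np.sum((ll3u(c, gr_inf, 10.0**log_gec50, h) - y) ** 2))
    dof = max(n - 3, 1)
    return DoseResponseFit(
        sample_id=sample_id, drug=drug, response=response,
        gr_inf=float(gr_inf), gec50=float(10.0**log_gec50), h=float(h),
        rse=float(np.sqrt(ssr / dof)), converged=True, n_points=n,
        c_min=c_min, c_max=c_max,
    )


def fit_library(
    growth: pd.DataFrame,
    response: str = "gr",
    *,
    aggregate_replicates: bool = False,
) -> list[DoseResponseFit]:
    """Fit one LL.3u curve per sample–drug pair from a growth-metrics table.

    ``response="gr"`` fits the ``gr_value`` column, ``"area"`` the
    ``normalized_relative_area`` column — the identical optimizer on a
    different response column.  By default all replicate-level points are
    passed to the fitter unaveraged; ``aggregate_replicates=True`` fits the
    per-concentration replicate means instead.
    """
    col = {"gr": "gr_value", "area": "normalized_relative_area"}[response]
    treated = growth[growth["concentration"] > 0]
    fits = []
    for (sample_id, drug), grp in treated.groupby(["sample_id", "drug"], sort=True):
        if aggregate_replicates:
            grp = grp.groupby("concentration", as_index=False)[col].mean()
        fits.append(
            fit_ll3u(
                grp["concentration"].to_numpy(), grp[col].to_numpy(),
                sample_id=str(sample_id), drug=str(drug), response=response,
            )
        )
    return fits


def fits_to_frame(fits: list[DoseResponseFit]) -> pd.DataFrame:
    """Tabulate fits, one row per sample–drug–readout (RSE included)."""
    return pd.DataFrame([f.__dict__ for f in fits])


def infer_curve(
    fit: DoseResponseFit,
    c_min: float | None = None,
    c_max: float | None = None,
    n_points: int = N_CURVE_POINTS,
) -> InferredCurve:
    """Evaluate the fitted curve at ``n_points`` uniformly spaced (linear)
    concentrations spanning the tested range."""
    if not fit.converged:
        raise ValueError(f"cannot infer a curve from a non-converged fit: {fit.message}")
    c_min = fit.c_min if c_min is None else c_min
    c_max = fit.c_max if c_max is None else c_max
    if not c_min < c_max:
        raise ValueError("c_min must be < c_max")
    grid = np.linspace(c_min, c_max, n_points)
    return InferredCurve(concentrations=grid, responses=fit.predict(grid))


def library_mean_curve(curves: list[InferredCurve], stat: str = "mean") -> InferredCurve:
    """Pointwise mean (or median) inferred curve across samples."""
    if not curves:
        raise ValueError("no curves")
    grid = curves[0].concentrations
    for cv in curves[1:]:
        if cv.concentrations.shape != grid.shape or not np.allclose(cv.concentrations, grid):
            raise ValueError("curves must share an identical concentration grid")
    stacked = np.vstack([cv.responses for cv in curves])
    if stat == "mean":
        y = stacked.mean(axis=0)
    elif stat == "median":
        y = np.median(stacked, axis=0)
    else:
        raise ValueError("stat must be 'mean' or 'median'")
    return InferredCurve(concentrations=grid.copy(), responses=y)
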