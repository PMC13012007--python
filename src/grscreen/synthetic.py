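"""Synthetic screen data with known ground truth.

Real PDT screens are not publicly deposited, so every downstream module is
exercised against data generated here:

* :func:`generate_library` — a library of virtual PDT samples with
  heterogeneous control growth rates and known true dose–response parameters.
  Treated-well growth is constructed by *inverting* the GR formula, so the
  per-replicate GR value of a noise-free well equals the sample's true GR(c)
  exactly; parameter recovery by the fitting modules is then a meaningful
  end-to-end check.
* :func:`generate_idealized_samples` — ten deterministic samples that share
  identical relative drug sensitivity but differ in control growth rate
  (day-7 control relative total area 10 down to 1.5).  Each concentration
  step removes a further 20% of the net growth increment, so the top step is
  exact cytostasis (relative area 1, GR 0) for every sample.  These are the
  substrate of the growth-rate-bias study.
* :func:`generate_image_timecourse` — confocal-like z-stacks of growing
  blobs, each sharp in exactly one plane, with exact ground-truth masks for
  validating the imaging stage.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .design import DEFAULT_DESIGN, DrugSeries, PlateDesign
from .dose_response import ll3u

__all__ = [
    "LL3uParams",
    "SyntheticSampleSpec",
    "IDEALIZED_GROWTH_RATES",
    "Blob",
    "SyntheticImageSpec",
    "AREA_COLUMNS",
    "draw_sample_specs",
    "generate_library",
    "generate_idealized_samples",
    "generate_image_timecourse",
    "write_image_timecourse",
]

#: Column order of the shared long-format area table.
AREA_COLUMNS = ["sample_id", "drug", "concentration", "unit", "replicate", "day", "area"]

#: Day-7 control relative total areas of the ten idealized samples, which are
#: named after these values.
IDEALIZED_GROWTH_RATES = (10.0, 5.0, 4.0, 3.0, 2.0, 1.9, 1.8, 1.7, 1.6, 1.5)


@dataclass(frozen=True)
class LL3uParams:
    """True three-parameter log-logistic parameters of a synthetic sample.

    ``gr_inf`` is the lower asymptote (response at infinite concentration),
    ``gec50`` the midpoint concentration and ``h`` the Hill-type slope; the
    upper asymptote is fixed at 1.
    """

    gr_inf: float
    gec50: float
    h: float

    def __post_init__(self) -> None:
        if not (-1.0 <= self.gr_inf < 1.0):
            raise ValueError("gr_inf must lie in [-1, 1)")
        if self.gec50 <= 0:
            raise ValueError("gec50 must be positive")
        if self.h <= 0:
            raise ValueError("h must be positive")


@dataclass(frozen=True)
class SyntheticSampleSpec:
    """Ground truth for one virtual PDT sample."""

    sample_id: str
    control_day7_relative_area: float
    true_params: dict[str, LL3uParams]
    noise_sd: float = 0.0
    baseline_area: float = 30_000.0

    def __post_init__(self) -> None:
        if self.control_day7_relative_area <= 1.0:
            raise ValueError("control growth must exceed 1 (net growth required)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.baseline_area <= 0:
            raise ValueError("baseline_area must be positive")


def _treated_growth(control_growth: float, gr: float) -> float:
    """Relative total area whose GR value against ``control_growth`` is ``gr``.

    Inverts GR = 2**(log2(g_t)/log2(g_c)) - 1, i.e.
    log2(g_t) = log2(1 + GR) * log2(g_c).  Requires GR > -1.
    """
    if gr <= -1.0:
        raise ValueError("GR values <= -1 have no finite growth-rate preimage")
    return float(2.0 ** (np.log2(1.0 + gr) * np.log2(control_growth)))


def draw_sample_specs(
    n_samples: int,
    design: PlateDesign = DEFAULT_DESIGN,
    *,
    seed: int = 0,
    noise_sd: float = 0.05,
    growth_range: tuple[float, float] = (1.3, 4.43),
    gr_inf_range: tuple[float, float] = (-0.3, 0.4),
    h_range: tuple[float, float] = (0.8, 2.5),
) -> list[SyntheticSampleSpec]:
    """Draw random sample specs emulating a successful PDT library.

    Control day-7 growth is log-uniform inside ``growth_range`` (default keeps
    every sample above the 1.2 culture-success threshold while spanning the
    heterogeneity observed in real libraries, whose control relative areas
    range from about 1.07 to 4.43).  Each drug's true GEC50 is log-uniform over
    the middle three decades of its tested range so the curve midpoint is
    always identifiable from the data.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_samples):
        growth = float(np.exp(rng.uniform(*np.log(growth_range))))
        params = {}
        for drug in design.drugs:
            lo, hi = drug.concentrations[1], drug.concentrations[-2]
            gec50 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            gr_inf = float(rng.uniform(*gr_inf_range))
            h = float(np.exp(rng.uniform(*np.log(h_range))))
            params[drug.name] = LL3uParams(gr_inf=gr_inf, gec50=gec50, h=h)
        baseline = float(rng.lognormal(mean=np.log(30_000.0), sigma=0.2))
        specs.append(
            SyntheticSampleSpec(
                sample_id=f"S{i + 1:02d}",
                control_day7_relative_area=growth,
                true_params=params,
                noise_sd=noise_sd,
                baseline_area=baseline,
            )
        )
    return specs


def _well_rows(
    sample_id: str,
    drug: str,
    concentration: float,
    unit: str,
    replicate: int,
    baseline: float,
    growth_day7: float,
    days: tuple[int, ...],
    rng: np.random.Generator | None,
    noise_sd: float,
) -> list[dict]:
    """Rows for one well: geometric growth from day 1 to the day-7 target.

    area(day) = area(1) * g**((day-1)/6) * noise, noise log-normal per
    imaged day after baseline.  Areas are clamped positive (log-normal noise
    already guarantees this; the clamp guards degenerate inputs).
    """
    rows = []
    for day in days:
        area = baseline * growth_day7 ** ((day - 1) / 6.0)
        if day != 1 and noise_sd > 0 and rng is not None:
            area *= float(rng.lognormal(mean=0.0, sigma=noise_sd))
        if area <= 0:  # pragma: no cover - log-normal noise cannot reach 0
            warnings.warn("non-positive synthetic area clamped", stacklevel=2)
            area = np.finfo(float).tiny
        rows.append(
            {
                "sample_id": sample_id,
                "drug": drug,
                "concentration": concentration,
                "unit": unit,
                "replicate": replicate,
                "day": day,
                "area": area,
            }
        )
    return rows


def simulate_sample(
    spec: SyntheticSampleSpec,
    design: PlateDesign = DEFAULT_DESIGN,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Long-format area table for one sample under ``design``."""
    if rng is None:
        rng = np.random.default_rng(0)
    g_ctrl = spec.control_day7_relative_area
    rows: list[dict] = []
    for rep in range(1, design.n_replicates + 1):
        rows += _well_rows(
            spec.sample_id, design.vehicle_label, 0.0, "", rep,
            spec.baseline_area, g_ctrl, design.imaging_days, rng, spec.noise_sd,
        )
    for drug in design.drugs:
        p = spec.true_params[drug.name]
        for conc in drug.concentrations:
            gr_true = ll3u(conc, p.gr_inf, p.gec50, p.h)
            g_treated = _treated_growth(g_ctrl, gr_true)
            for rep in range(1, design.n_replicates + 1):
                rows += _well_rows(
                    spec.sample_id, drug.name, conc, drug.unit, rep,
                    spec.baseline_area, g_treated, design.imaging_days, rng,
                    spec.noise_sd,
                )
    return pd.DataFrame(rows, columns=AREA_COLUMNS)


def generate_library(
    n_samples: int = 16,
    design: PlateDesign = DEFAULT_DESIGN,
    *,
    seed: int = 0,
    noise_sd: float = 0.05,
    specs: list[SyntheticSampleSpec] | None = None,
) -> tuple[pd.DataFrame, list[SyntheticSampleSpec]]:
    """Generate a synthetic PDT library.

    Returns the long-format area table and the ground-truth specs.  With
    ``noise_sd=0`` the per-replicate GR value of every treated well equals
    the sample's true GR(c) exactly, so downstream fitting should recover
    each sample's true parameters.  Deterministic for a given seed.
    """
    if specs is None:
        specs = draw_sample_specs(n_samples, design, seed=seed, noise_sd=noise_sd)
    rng = np.random.default_rng(seed + 1)
    frames = [simulate_sample(s, design, rng) for s in specs]
    table = pd.concat(frames, ignore_index=True)
    table.attrs["seed"] = seed
    return table, specs


def generate_idealized_samples(
    design: PlateDesign = DEFAULT_DESIGN,
    *,
    growth_rates: tuple[float, ...] = IDEALIZED_GROWTH_RATES,
    reduction_per_step: float = 0.20,
    baseline_area: float = 10_000.0,
    reduction_applies_to: str = "net_growth",
) -> pd.DataFrame:
    """Ten idealized samples with equal sensitivity but unequal growth rate.

    Each sample is named after its day-7 control relative total area.  For
    concentration step ``i`` (1..5), the day-7 relative area is::

        1 + (control_relative_area - 1) * (1 - reduction_per_step * i)

    i.e. each step removes a further 20% of the *net growth increment*
    relative to vehicle; step 5 removes 100% of it, leaving relative area
    exactly 1 — complete cytostasis, GR = 0 — for every sample.  Technical
    replicates are present but identical, and only days 1 and 7 are
    generated.  Fully deterministic.

    ``reduction_applies_to="relative_area"`` instead scales the relative
    area itself by ``(1 - reduction_per_step * i)``; that interpretation
    drives relative area toward 0 (total area loss) rather than 1 and is
    provided only for comparison.
    """
    if reduction_applies_to not in ("net_growth", "relative_area"):
        raise ValueError("reduction_applies_to must be 'net_growth' or 'relative_area'")
    n_steps = len(design.drugs[0].concentrations)
    rows: list[dict] = []
    for g in growth_rates:
        sample_id = f"{g:g}"
        for rep in range(1, design.n_replicates + 1):
            rows += _well_rows(
                sample_id, design.vehicle_label, 0.0, "", rep,
                baseline_area, g, (1, 7), None, 0.0,
            )
        for drug in design.drugs:
            if len(drug.concentrations) != n_steps:
                raise ValueError("all drugs must share the same number of steps")
            for i, conc in enumerate(drug.concentrations, start=1):
                frac = 1.0 - reduction_per_step * i
                if reduction_applies_to == "net_growth":
                    rel = 1.0 + (g - 1.0) * frac
                else:
                    rel = max(g * frac, 1e-6)
                for rep in range(1, design.n_replicates + 1):
                    rows += _well_rows(
                        sample_id, drug.name, conc, drug.unit, rep,
                        baseline_area, rel, (1, 7), None, 0.0,
                    )
    return pd.DataFrame(rows, columns=AREA_COLUMNS)


# ---------------------------------------------------------------------------
# Synthetic well images


@dataclass(frozen=True)
class Blob:
    """A disc-shaped tumoroid stand-in.

    ``center`` is (row, col) in pixels, ``radius`` the day-1 radius,
    ``growth_per_day`` the multiplicative radius growth factor and
    ``focal_plane`` the z index where the blob is in focus.
    """

    center: tuple[float, float]
    radius: float
    growth_per_day: float = 1.0
    focal_plane: int = 0


@dataclass(frozen=True)
class SyntheticImageSpec:
    """A synthetic well: image geometry, blobs, optics and noise."""

    shape: tuple[int, int] = (256, 256)
    z_planes: int = 3
    blobs: tuple[Blob, ...] = ()
    blur_sd: float = 3.0
    noise_sd: float = 0.0
    background: float = 0.1
    foreground: float = 0.9
    seed: int = 0

    def validate(self, days: tuple[int, ...]) -> None:
        h, w = self.shape
        for b in self.blobs:
            if not 0 <= b.focal_plane < self.z_planes:
                raise ValueError(f"focal plane {b.focal_plane} outside stack")
            r_max = b.radius * b.growth_per_day ** (max(days) - 1)
            r0, c0 = b.center
            if r0 - r_max < 0 or r0 + r_max > h - 1 or c0 - r_max < 0 or c0 + r_max > w - 1:
                raise ValueError(
                    f"blob at {b.center} escapes the {h}x{w} frame by day {max(days)}"
                )


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_image_timecourse(
    spec: SyntheticImageSpec,
    days: tuple[int, ...] = (1, 7),
) -> dict[int, tuple[np.ndarray, np.ndarray, int]]:
    """Per day: a (z, h, w) float stack, the ground-truth mask and its area.

    Each blob is rendered sharp in its focal plane and Gaussian-blurred in
    every other plane in proportion to the plane distance, mimicking the
    defocus of a confocal z-stack; the ground truth is the union of the
    sharp discs (exact rasterized pixel counts).
    """
    spec.validate(tuple(days))
    rng = np.random.default_rng(spec.seed)
    out: dict[int, tuple[np.ndarray, np.ndarray, int]] = {}
    for day in days:
        mask = np.zeros(spec.shape, dtype=bool)
        stack = np.full((spec.z_planes,) + spec.shape, spec.background, dtype=float)
        for b in spec.blobs:
            radius = b.radius * b.growth_per_day ** (day - 1)
            disc = _disc_mask(spec.shape, b.center, radius)
            mask |= disc
            signal = disc.astype(float) * (spec.foreground - spec.background)
            for z in range(spec.z_planes):
                dist = abs(z - b.focal_plane)
                layer = signal if dist == 0 else ndi.gaussian_filter(signal, spec.blur_sd * dist)
                stack[z] = np.maximum(stack[z], spec.background + layer)
        if spec.noise_sd > 0:
            stack = stack + rng.normal(0.0, spec.noise_sd, size=stack.shape)
        out[day] = (stack, mask, int(mask.sum()))
    return out


def write_image_timecourse(
    spec: SyntheticImageSpec,
    days: tuple[int, ...],
    out_dir,
    well_id: str = "A01",
) -> pd.DataFrame:
    """Write single-plane TIFFs as ``<well>/day<d>/z<k>.tif`` + ground_truth.csv."""
    import tifffile
    from pathlib import Path

    out_dir = Path(out_dir)
    records = []
    for day, (stack, _mask, area) in generate_image_timecourse(spec, days).items():
        day_dir = out_dir / well_id / f"day{day}"
        day_dir.mkdir(parents=True, exist_ok=True)
        for z in range(stack.shape[0]):
            tifffile.imwrite(day_dir / f"z{z}.tif", stack[z].astype(np.float32))
        records.append({"well": well_id, "day": day, "true_area_px": area})
    truth = pd.DataFrame(records)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return truth
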