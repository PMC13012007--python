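"""Z-stack to tumoroid-covered area.

Wells are imaged as confocal z-stacks so that tumoroids suspended at
different depths of the gel droplet are each captured in focus somewhere in
the stack.  The pipeline is: best-focus 2D projection (per-pixel, the plane
maximizing local intensity variance), binarization (Otsu threshold by
default, small objects removed, holes filled), and area quantification in
pixels (or physical units when a pixel size is supplied).  The readout is
total covered area only — no per-organoid tracking or morphology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

__all__ = [
    "ZStack",
    "AreaMeasurement",
    "best_focus_projection",
    "binarize",
    "measure_area",
    "process_well_timecourse",
    "read_zstack",
]


@dataclass(frozen=True)
class ZStack:
    """An ordered stack of equally shaped 2D intensity planes for one well/day."""

    planes: np.ndarray  # (z, h, w)
    well_id: str = ""
    day: int = 1

    def __post_init__(self) -> None:
        p = self.planes
        if p.ndim != 3 or p.shape[0] < 1:
            raise ValueError("planes must be a (z, h, w) array with z >= 1")
        if not np.all(np.isfinite(p)):
            raise ValueError("plane intensities must be finite")


@dataclass(frozen=True)
class AreaMeasurement:
    well_id: str
    day: int
    area: float
    coverage: float  # foreground fraction of the frame, in [0, 1]

    def __post_init__(self) -> None:
        if self.area < 0 or not 0.0 <= self.coverage <= 1.0:
            raise ValueError("invalid area measurement")


def local_variance(image: np.ndarray, window: int) -> np.ndarray:
    """Variance of intensities in a window x window neighborhood of each pixel."""
    img = np.asarray(image, dtype=float)
    mean = ndi.uniform_filter(img, size=window)
    mean_sq = ndi.uniform_filter(img * img, size=window)
    return np.maximum(mean_sq - mean * mean, 0.0)


def best_focus_projection(stack: ZStack | np.ndarray, window: int = 9) -> np.ndarray:
    """Best-focus 2D projection: per pixel, take the plane with the highest
    local intensity variance (sharpest) in a ``window`` neighborhood.

    A single-plane stack is returned unchanged.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    planes = stack.planes if isinstance(stack, ZStack) else np.asarray(stack, dtype=float)
    if planes.shape[0] == 1:
        return planes[0].copy()
    sharpness = np.stack([local_variance(p, window) for p in planes])
    best = np.argmax(sharpness, axis=0)
    return np.take_along_axis(planes, best[None], axis=0)[0]


def binarize(
    image: np.ndarray,
    method: str = "otsu",
    min_object_px: int = 50,
    threshold: float | None = None,
) -> np.ndarray:
    """Foreground (tumoroid) mask of a projection image.

    ``method="otsu"`` thresholds by Otsu's criterion (invariant to affine
    intensity rescaling); ``method="fixed"`` uses the supplied ``threshold``.
    Objects below ``min_object_px`` pixels are removed and holes are filled.
    A constant image yields an empty mask with a warning — no threshold can
    separate foreground there.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image intensities must be finite")
    if img.max() == img.min():
        warnings.warn("constant image: returning empty mask")
        return np.zeros(img.shape, dtype=bool)
    if method == "otsu":
        thr = threshold_otsu(img)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown binarization method: {method!r}")
    mask = img > thr
    if min_object_px > 1:
        # removes objects strictly smaller than min_object_px
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    return ndi.binary_fill_holes(mask)


def measure_area(
    mask: np.ndarray,
    pixel_size: float = 1.0,
    well_id: str = "",
    day: int = 1,
) -> AreaMeasurement:
    """Covered area = foreground pixel count x pixel_size**2."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise ValueError("mask must be boolean")
    n_fg = int(mask.sum())
    return AreaMeasurement(
        well_id=well_id,
        day=day,
        area=n_fg * pixel_size**2,
        coverage=n_fg / mask.size,
    )


def process_well_timecourse(
    stacks_by_day: dict[int, ZStack | np.ndarray],
    *,
    window: int = 9,
    method: str = "otsu",
    min_object_px: int = 50,
    pixel_size: float = 1.0,
    well_id: str = "",
) -> list[AreaMeasurement]:
    """Project, binarize and measure every imaging day of one well.

    Day 1 must be present (relative total area needs the baseline) and at
    least two imaging days are required.  Days are processed in order; a
    missing day is simply absent from the output, never interpolated.
    """
    days = sorted(stacks_by_day)
    if 1 not in days:
        raise ValueError("day-1 stack required as the relative-area baseline")
    if len(days) < 2:
        raise ValueError("need stacks for at least two imaging days")
    out = []
    for day in days:
        proj = best_focus_projection(stacks_by_day[day], window=window)
        mask = binarize(proj, method=method, min_object_px=min_object_px)
        out.append(measure_area(mask, pixel_size=pixel_size, well_id=well_id, day=day))
    return out


def read_zstack(path, well_id: str = "", day: int = 1) -> ZStack:
    """Read a z-stack from a multi-page TIFF or a directory of z*.tif planes."""
    import tifffile

    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("z*.tif")) + sorted(path.glob("z*.tiff"))
        if not files:
            raise FileNotFoundError(f"no z*.tif planes under {path}")
        planes = np.stack([tifffile.imread(f) for f in files]).astype(float)
    else:
        arr = np.asarray(tifffile.imread(path), dtype=float)
        planes = arr[None] if arr.ndim == 2 else arr
    return ZStack(planes=planes, well_id=well_id, day=day)
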