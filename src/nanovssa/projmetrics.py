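"""Conventional-TEM 2D analysis of the zero-tilt image.

Replicates the classic workflow used to validate the tomographic
measurements: segment the particles in the 0-degree micrograph, measure
the projected area, convert it to the equivalent circle diameter (ECD),
and estimate surface area and volume with the perfect-sphere formulas
4 pi r^2 and 4/3 pi r^3, r = ECD/2.  Sphericity (second central moments,
1 for a disk) quantifies how defensible the sphere assumption is.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as _ndi
from skimage import filters as _skfilters
from skimage import measure as _skmeasure

from .core import TiltSeries

__all__ = [
    "ProjectedParticle",
    "segment_zero_tilt",
    "ecd",
    "sphere_surface_area",
    "sphere_volume",
    "sphericity",
    "analyze_zero_tilt",
]

#: Gaussian pre-smoothing (px) applied before thresholding the noisy image
DEFAULT_SMOOTH_SIGMA = 1.0
DEFAULT_MIN_PIXELS = 30


@dataclass
class ProjectedParticle:
    label: int
    pixel_area: int
    area_nm2: float
    ecd_nm: float
    sphericity: float
    calc_sphere_area_nm2: float
    calc_sphere_volume_nm3: float


def segment_zero_tilt(ts: TiltSeries, threshold: float | None = None,
                      smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
                      min_pixels: int = DEFAULT_MIN_PIXELS,
                      method: str = "background"):
    """Segment particles in the minimal-|angle| image of the series.

    A light Gaussian blur precedes thresholding; regions are 8-connected,
    border-touching regions are excluded and regions below ``min_pixels``
    despeckled.  Returns the 2D label image (labels ordered by decreasing
    size).

    The default threshold is the background floor: median + 3 robust sigma
    (MAD-based) of the smoothed image.  A projected sphere is a dome whose
    thickness falls continuously to zero at the rim, so any threshold well
    above the noise floor erodes the projected area and biases the ECD low;
    the floor rule keeps the full silhouette while excluding background
    noise.  ``method="otsu"`` or an explicit ``threshold`` override it.

    Particles that overlap in projection merge into a single region —
    the inherent superposition limitation of 2D analysis that the 3D
    pipeline exists to remove.
    """
    img = ts.images[ts.zero_tilt_index].astype(np.float64)
    if smooth_sigma > 0:
        img = _ndi.gaussian_filter(img, smooth_sigma)
    if threshold is None:
        if img.min() == img.max():
            raise ValueError("blank zero-tilt image: nothing to segment")
        if method == "otsu":
            threshold = float(_skfilters.threshold_otsu(img))
        elif method == "background":
            med = float(np.median(img))
            mad = float(np.median(np.abs(img - med)))
            threshold = med + 3.0 * 1.4826 * mad + 1e-6 * (img.max() - med)
        else:
            raise ValueError(f"unknown threshold method {method!r}")
    fg = img >= threshold
    raw, n = _ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("no foreground in the zero-tilt image at this threshold")
    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    border_ids = np.unique(np.concatenate([
        raw[0], raw[-1], raw[:, 0], raw[:, -1]]))
    keep[border_ids[border_ids > 0]] = False
    counts = np.bincount(raw.ravel(), minlength=n + 1)
    keep[counts < min_pixels] = False
    kept = np.nonzero(keep)[0]
    if len(kept) == 0:
        raise ValueError("no region survived border exclusion and despeckling")
    order = kept[np.argsort(counts[kept])[::-1]]
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order] = np.arange(1, len(order) + 1)
    return remap[raw]


def ecd(area_nm2: float) -> float:
    """Equivalent circle diameter: 2 sqrt(area / pi)."""
    if not area_nm2 > 0:
        raise ValueError(f"area must be > 0, got {area_nm2}")
    return 2.0 * math.sqrt(area_nm2 / math.pi)


def sphere_surface_area(ecd_nm: float) -> float:
    """4 pi r^2 with r = ECD/2."""
    if not ecd_nm > 0:
        raise ValueError(f"ecd must be > 0, got {ecd_nm}")
    r = ecd_nm / 2.0
    return 4.0 * math.pi * r * r


def sphere_volume(ecd_nm: float) -> float:
    """4/3 pi r^3 with r = ECD/2."""
    if not ecd_nm > 0:
        raise ValueError(f"ecd must be > 0, got {ecd_nm}")
    r = ecd_nm / 2.0
    return 4.0 / 3.0 * math.pi * r ** 3


def sphericity(region_mask: np.ndarray) -> float:
    """Roundness from second central moments: sqrt(lambda_min/lambda_max)
    of the 2x2 covariance of pixel positions.  1 for a disk; a 2:1 ellipse
    gives 0.5.  Rotation-invariant."""
    yy, xx = np.nonzero(region_mask)
    if len(yy) < 10:
        raise ValueError("region too small for moment analysis (< 10 px)")
    y = yy - yy.mean()
    x = xx - xx.mean()
    cov = np.array([[np.mean(y * y), np.mean(y * x)],
                    [np.mean(y * x), np.mean(x * x)]])
    lam = np.linalg.eigvalsh(cov)
    if lam[1] <= 0:
        raise ValueError("degenerate (collinear) region")
    return float(math.sqrt(max(lam[0], 0.0) / lam[1]))


def analyze_zero_tilt(ts: TiltSeries, threshold: float | None = None,
                      smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
                      min_pixels: int = DEFAULT_MIN_PIXELS,
                      method: str = "background"):
    """Full 2D workflow: segment the 0-degree image and return per-particle
    :class:`ProjectedParticle` records (plus the label image)."""
    labels = segment_zero_tilt(ts, threshold, smooth_sigma, min_pixels, method)
    px2 = ts.pixel_size ** 2
    out = []
    for lab in range(1, int(labels.max()) + 1):
        mask = labels == lab
        npx = int(mask.sum())
        area = npx * px2
        d = ecd(area)
        out.append(ProjectedParticle(
            label=lab, pixel_area=npx, area_nm2=area, ecd_nm=d,
            sphericity=sphericity(mask),
            calc_sphere_area_nm2=sphere_surface_area(d),
            calc_sphere_volume_nm3=sphere_volume(d)))
    return out, labels
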