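"""Single-axis bright-field tilt-series acquisition under mass-thickness
contrast.

Projection images are line integrals of density along the tilted beam
direction ("thickness space", nm x density), which keeps the downstream
reconstruction problem linear.  The exponential bright-field intensity
model lives only inside :func:`add_noise`, which converts to counts,
applies shot and readout noise, and converts back.  Stage jitter is
simulated as per-image random translations whose ground truth is recorded
for the alignment stage.

Defaults emulate routine acquisition: +/-65 degree range at 1 degree
increments (a single-axis series with the corresponding missing wedge).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import TiltSeries, Volume3D
from .projector import get_projector

__all__ = ["AcquisitionParams", "project_series", "add_noise", "apply_jitter"]


@dataclass
class AcquisitionParams:
    """Acquisition geometry and noise settings.

    dose is the expected electron count per pixel through vacuum;
    attenuation_lambda (nm) sets bright-field contrast via
    I = dose * exp(-thickness / lambda).
    """

    tilt_min: float = -65.0
    tilt_max: float = 65.0
    increment: float = 1.0
    dose: float = 2000.0
    readout_sigma: float = 0.0
    attenuation_lambda: float = 100.0
    jitter_max: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tilt_min < self.tilt_max:
            raise ValueError("tilt_min must be < tilt_max")
        if not self.increment > 0:
            raise ValueError("increment must be > 0")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.jitter_max < 0:
            raise ValueError("jitter_max must be >= 0")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.tilt_min, self.tilt_max + self.increment / 2,
                         self.increment)


def project_series(volume: Volume3D, params: AcquisitionParams,
                   axis_offset_px: float = 0.0) -> TiltSeries:
    """Simulate the noise-free tilt series of a phantom volume.

    Each image is the line integral of density along the beam after rotating
    the specimen about the y axis (bilinear sampling), scaled by voxel_size
    so pixel values are thickness x density in nm.  ``axis_offset_px``
    displaces the physical rotation axis from the image centre; the returned
    metadata does NOT record it (it is the unknown the alignment stage must
    recover), only ``tilt_axis_offset = 0``.
    """
    nz, ny, nx = volume.shape
    if min(nz, nx) < 4:
        raise ValueError("volume too small to rotate and project")
    proj = get_projector(nz, nx, params.angles, axis_offset_px)
    images = proj.forward(volume.values) * volume.voxel_size
    return TiltSeries(images, params.angles, pixel_size=volume.voxel_size)


def add_noise(ts: TiltSeries, params: AcquisitionParams) -> TiltSeries:
    """Shot + readout noise via the bright-field intensity model.

    I = dose * exp(-p / lambda) is Poisson-sampled and Gaussian readout
    noise added; the returned stack stores -lambda * log(I / dose), so
    downstream stages keep seeing projection-like thickness values.
    """
    if params.dose <= 0 and params.readout_sigma == 0:
        warnings.warn("dose <= 0 and readout_sigma == 0: add_noise is the identity")
        return ts.copy()
    rng = np.random.default_rng(params.seed)
    lam = params.attenuation_lambda
    if params.dose <= 0:
        noisy = ts.images + rng.normal(0.0, params.readout_sigma, ts.images.shape)
    else:
        expected = params.dose * np.exp(-ts.images.astype(np.float64) / lam)
        counts = rng.poisson(expected).astype(np.float64)
        if params.readout_sigma > 0:
            counts += rng.normal(0.0, params.readout_sigma, counts.shape)
        counts = np.maximum(counts, 0.25)  # guard the log for zero-count pixels
        noisy = -lam * np.log(counts / params.dose)
    out = ts.copy()
    out.images = noisy.astype(np.float32)
    return out


def apply_jitter(ts: TiltSeries, params: AcquisitionParams) -> TiltSeries:
    """Translate every image by a seeded uniform shift in
    [-jitter_max, jitter_max]^2 px and record the truth in applied_shifts."""
    rng = np.random.default_rng(params.seed + 1)
    n = len(ts)
    if params.jitter_max == 0:
        out = ts.copy()
        out.applied_shifts = np.zeros((n, 2))
        return out
    shifts = rng.uniform(-params.jitter_max, params.jitter_max, size=(n, 2))
    images = np.empty_like(ts.images)
    for i in range(n):
        images[i] = ndimage.shift(ts.images[i], shifts[i], order=3,
                                  mode="constant", cval=float(ts.images[i].min()))
    out = ts.copy()
    out.images = images
    out.applied_shifts = shifts
    return out
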