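"""Tomographic reconstruction: WBP, SIRT and ART.

All three share the sparse forward projector of the acquisition model, so
SIRT's back-projection step is the exact adjoint of the forward step —
the matched pair keeps the simultaneous iteration stable.  For bright-field
series of nanoparticles, SIRT in its 10–20 iteration regime gives the best
signal-to-noise ratio and is the pipeline default (15 iterations); WBP is
fast and is also used internally for tilt-axis scoring; ART applies damped
Kaczmarz sweeps per projection.

Reconstructions are returned in density units (the phantom's interior
density is ~1), obtained by dividing projections by the pixel size before
inversion.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage as _ndi

from .core import TiltSeries, Volume3D
from .projector import get_projector

__all__ = ["wbp", "sirt", "art", "reconstruction_quality"]

#: ramp-filter rolloff start, as a fraction of the Nyquist frequency
RAMP_ROLLOFF = 0.9


def _geometry(ts: TiltSeries, output_nz: int | None, axis_offset: float | None):
    if len(ts) == 0:
        raise ValueError("empty tilt series")
    n, ny, nx = ts.images.shape
    nz = nx if output_nz is None else int(output_nz)
    off = ts.tilt_axis_offset if axis_offset is None else float(axis_offset)
    return get_projector(nz, nx, ts.angles, off), nz, ny, nx


def _ramp_filter(images: np.ndarray) -> np.ndarray:
    """Frequency-domain ramp along x with raised-cosine rolloff beyond
    RAMP_ROLLOFF x Nyquist, applied per image row (zero-padded FFT)."""
    n, ny, nx = images.shape
    npad = 2 * nx
    f = np.fft.rfftfreq(npad)  # cycles/sample, up to 0.5
    h = np.abs(f)
    fc = RAMP_ROLLOFF * 0.5
    hi = np.abs(f) > fc
    h[hi] *= 0.5 * (1 + np.cos(np.pi * (np.abs(f[hi]) - fc) / (0.5 - fc)))
    spec = np.fft.rfft(images, n=npad, axis=-1)
    return np.fft.irfft(spec * h, n=npad, axis=-1)[..., :nx].astype(np.float32)


def wbp(ts: TiltSeries, output_nz: int | None = None,
        axis_offset: float | None = None) -> Volume3D:
    """Weighted (filtered) back-projection."""
    proj, nz, ny, nx = _geometry(ts, output_nz, axis_offset)
    filtered = _ramp_filter(ts.images / ts.pixel_size)
    vol = proj.backward(filtered) * (np.pi / (2 * len(ts)))
    return Volume3D(vol, ts.pixel_size)


def sirt(ts: TiltSeries, n_iter: int = 15, relax: float = 1.0,
         output_nz: int | None = None, axis_offset: float | None = None,
         return_residuals: bool = False):
    """Simultaneous iterative reconstruction technique.

    x <- x + relax * C^-1 A^T R^-1 (b - A x), with R and C the diagonal row
    and column sums of the system matrix; zero initialisation, so a single
    iteration is a normalised back-projection.  On consistent (noise-free)
    data the projection residual norm decreases monotonically.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 < relax <= 1:
        raise ValueError(f"relax must be in (0, 1], got {relax}")
    proj, nz, ny, nx = _geometry(ts, output_nz, axis_offset)
    B = proj._images_to_sino(ts.images / ts.pixel_size)
    r_inv = np.where(proj.row_sum > 1e-8, 1.0 / np.maximum(proj.row_sum, 1e-8), 0.0)
    c_inv = np.where(proj.col_sum > 1e-8, 1.0 / np.maximum(proj.col_sum, 1e-8), 0.0)
    X = np.zeros((nz * nx, ny), dtype=np.float32)
    residuals = []
    for _ in range(n_iter):
        resid = B - proj.A @ X
        residuals.append(float(np.linalg.norm(resid)))
        X += relax * c_inv[:, None] * (proj.A.T @ (r_inv[:, None] * resid))
    vol = Volume3D(proj._mat_to_vol(X, ny), ts.pixel_size)
    return (vol, residuals) if return_residuals else vol


def art(ts: TiltSeries, n_iter: int = 10, relax: float = 0.25,
        output_nz: int | None = None, axis_offset: float | None = None) -> Volume3D:
    """Algebraic reconstruction technique: damped block-Kaczmarz sweeps,
    one block per tilt image, in ascending angle order.  Deterministic."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 < relax <= 1:
        raise ValueError(f"relax must be in (0, 1], got {relax}")
    proj, nz, ny, nx = _geometry(ts, output_nz, axis_offset)
    B = proj._images_to_sino(ts.images / ts.pixel_size)
    blocks = []
    for a in range(len(ts)):
        Aa = proj.angle_block(a)
        rn2 = np.asarray(Aa.multiply(Aa).sum(axis=1)).ravel()
        blocks.append((Aa, np.where(rn2 > 1e-8, 1.0 / np.maximum(rn2, 1e-8), 0.0)))
    X = np.zeros((nz * nx, ny), dtype=np.float32)
    for _ in range(n_iter):
        for a, (Aa, rn_inv) in enumerate(blocks):
            resid = B[a * nx:(a + 1) * nx] - Aa @ X
            X += relax * (Aa.T @ (rn_inv[:, None] * resid))
    return Volume3D(proj._mat_to_vol(X, ny), ts.pixel_size)


_SNR_CAP_DB = 99.0


def reconstruction_quality(recon: Volume3D, truth: Volume3D) -> dict:
    """Voxelwise fidelity metrics of a reconstruction against its phantom.

    pearson_r over all voxels; snr_db = 10 log10(var(truth)/var(error))
    after affine intensity matching (capped at 99 dB for exact recovery);
    z_elongation = z/x extent ratio of the largest half-max component, the
    missing-wedge signature.
    """
    if recon.shape != truth.shape:
        raise ValueError(f"shape mismatch: {recon.shape} vs {truth.shape}")
    r = recon.values.astype(np.float64).ravel()
    t = truth.values.astype(np.float64).ravel()
    pearson = float(np.corrcoef(r, t)[0, 1])
    a, b = np.polyfit(r, t, 1)
    err = a * r + b - t
    vt, ve = float(np.var(t)), float(np.var(err))
    snr_db = _SNR_CAP_DB if ve <= vt * 10 ** (-_SNR_CAP_DB / 10) \
        else float(10 * np.log10(vt / ve))
    m = (a * recon.values + b)
    mask = m >= 0.5 * float(m.max())
    labels, n = _ndi.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        raise ValueError("no half-max component found")
    largest = int(np.argmax(_ndi.sum_labels(mask, labels, range(1, n + 1)))) + 1
    zz, _, xx = np.nonzero(labels == largest)
    z_ext = zz.max() - zz.min() + 1
    x_ext = xx.max() - xx.min() + 1
    return {"pearson_r": pearson, "snr_db": snr_db,
            "z_elongation": float(z_ext) / float(x_ext)}
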