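"""Parallel-beam projection operator for single-axis tilt geometry.

The tilt axis is the volume's y axis, so every y slice poses an independent
2D problem in the (z, x) plane.  The operator is materialised once as a
sparse matrix of bilinear interpolation footprints, shared by all y slices:
the forward projection of a volume is a single sparse matmul, and the exact
adjoint (the transpose) serves as the back-projector.  A matched
forward/back pair is what keeps SIRT iterations stable.

Geometry: for tilt angle theta the specimen is rotated about the y axis and
integrated along z.  Equivalently, the ray for detector column x' samples
the volume at

    z = cz + uz cos(t) - ux sin(t)
    x = cx + o + uz sin(t) + ux cos(t)

with uz = z' - cz, ux = x' - (cx + o), rotation centres cz = (nz-1)/2 and
cx = (nx-1)/2, and o the tilt-axis offset (px) from the image centre.  At
theta = 0 the sampling grid coincides with the voxel grid, so the zero-tilt
projection is an exact axis-aligned sum.
"""
from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = ["Projector", "get_projector"]


class Projector:
    """Sparse parallel-beam projector for a fixed set of tilt angles."""

    def __init__(self, n_z: int, n_x: int, angles_deg, axis_offset: float = 0.0):
        self.n_z = int(n_z)
        self.n_x = int(n_x)
        self.angles_deg = np.asarray(angles_deg, dtype=float)
        self.axis_offset = float(axis_offset)
        self.n_angles = len(self.angles_deg)
        self.A = self._build()
        # Row/column sums for SIRT normalisation; guarded against zeros
        # (rays that miss the grid, voxels never sampled).
        self.row_sum = np.asarray(self.A.sum(axis=1)).ravel()
        self.col_sum = np.asarray(self.A.sum(axis=0)).ravel()

    def _build(self) -> sparse.csr_matrix:
        nz, nx = self.n_z, self.n_x
        cz, cx = (nz - 1) / 2.0, (nx - 1) / 2.0
        o = self.axis_offset
        zp, xp = np.meshgrid(np.arange(nz), np.arange(nx), indexing="ij")
        uz = (zp - cz).ravel()
        ux = (xp - (cx + o)).ravel()
        det_col = xp.ravel()  # detector column of each sample point

        rows_all, cols_all, vals_all = [], [], []
        for a, ang in enumerate(self.angles_deg):
            t = np.deg2rad(ang)
            zi = cz + uz * np.cos(t) - ux * np.sin(t)
            xi = (cx + o) + uz * np.sin(t) + ux * np.cos(t)
            z0 = np.floor(zi).astype(np.int64)
            x0 = np.floor(xi).astype(np.int64)
            fz = zi - z0
            fx = xi - x0
            row = a * nx + det_col
            for dz, dx, w in (
                (0, 0, (1 - fz) * (1 - fx)),
                (0, 1, (1 - fz) * fx),
                (1, 0, fz * (1 - fx)),
                (1, 1, fz * fx),
            ):
                zc, xc = z0 + dz, x0 + dx
                ok = (w > 1e-12) & (zc >= 0) & (zc < nz) & (xc >= 0) & (xc < nx)
                rows_all.append(row[ok])
                cols_all.append(zc[ok] * nx + xc[ok])
                vals_all.append(w[ok].astype(np.float32))
        A = sparse.coo_matrix(
            (np.concatenate(vals_all),
             (np.concatenate(rows_all), np.concatenate(cols_all))),
            shape=(self.n_angles * nx, nz * nx),
        )
        return A.tocsr()

    # -- reshaping helpers -------------------------------------------------
    def _vol_to_mat(self, vol: np.ndarray) -> np.ndarray:
        nz, ny, nx = vol.shape
        return np.ascontiguousarray(vol.transpose(0, 2, 1)).reshape(nz * nx, ny)

    def _mat_to_vol(self, mat: np.ndarray, ny: int) -> np.ndarray:
        return mat.reshape(self.n_z, self.n_x, ny).transpose(0, 2, 1)

    def _sino_to_images(self, sino: np.ndarray, ny: int) -> np.ndarray:
        return sino.reshape(self.n_angles, self.n_x, ny).transpose(0, 2, 1)

    def _images_to_sino(self, images: np.ndarray) -> np.ndarray:
        n, ny, nx = images.shape
        return np.ascontiguousarray(images.transpose(0, 2, 1)).reshape(n * nx, ny)

    # -- operator application ---------------------------------------------
    def forward(self, vol: np.ndarray) -> np.ndarray:
        """Project a (nz, ny, nx) volume to an (n_angles, ny, nx) stack."""
        if vol.shape[0] != self.n_z or vol.shape[2] != self.n_x:
            raise ValueError("volume shape does not match projector geometry")
        sino = self.A @ self._vol_to_mat(np.asarray(vol, dtype=np.float32))
        return self._sino_to_images(sino, vol.shape[1])

    def backward(self, images: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`forward`: smear an image stack into a volume."""
        if images.shape[0] != self.n_angles or images.shape[2] != self.n_x:
            raise ValueError("image stack shape does not match projector geometry")
        mat = self.A.T @ self._images_to_sino(np.asarray(images, dtype=np.float32))
        return self._mat_to_vol(mat, images.shape[1])

    def angle_block(self, a: int) -> sparse.csr_matrix:
        """Rows of the system matrix belonging to tilt image ``a``."""
        return self.A[a * self.n_x:(a + 1) * self.n_x]


_CACHE: dict[tuple, Projector] = {}


def get_projector(n_z: int, n_x: int, angles_deg, axis_offset: float = 0.0) -> Projector:
    """Memoised projector lookup (construction is the expensive part)."""
    key = (int(n_z), int(n_x), tuple(np.round(np.asarray(angles_deg, float), 6)),
           round(float(axis_offset), 6))
    if key not in _CACHE:
        if len(_CACHE) > 16:  # bound memory across many geometries
            _CACHE.clear()
        _CACHE[key] = Projector(n_z, n_x, angles_deg, axis_offset)
    return _CACHE[key]
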