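"""Shared in-memory containers for the tomography pipeline.

All lengths are nanometres.  Volumes are indexed ``(z, y, x)`` with ``z``
the electron-beam direction at zero tilt and ``y`` the tilt axis.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Volume3D", "TiltSeries"]


@dataclass
class Volume3D:
    """A 3D scalar grid with isotropic voxel size.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Density values (arbitrary units; phantoms use 1 inside particles).
    voxel_size : float
        Isotropic voxel edge length in nm.
    origin : ndarray, shape (3,)
        Physical position (nm) of the voxel with index (0, 0, 0).
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("Volume3D requires a 3D grid with all dims >= 1")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Volume3D density values must be finite")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "Volume3D":
        return Volume3D(self.values.copy(), self.voxel_size, self.origin.copy())

    def with_values(self, values: np.ndarray) -> "Volume3D":
        return replace(self, values=values)


@dataclass
class TiltSeries:
    """Ordered stack of 2D projection images with per-image tilt angles.

    ``images`` has shape (n_angles, ny, nx); image rows run along the tilt
    axis (y) and columns along x, the direction perpendicular to it.
    Shifts are (dy, dx) pairs in pixels.
    """

    images: np.ndarray
    angles: np.ndarray
    pixel_size: float
    tilt_axis_rotation: float = 0.0  # in-plane angle of the tilt axis, deg
    tilt_axis_offset: float = 0.0    # offset of the axis from image centre, px
    applied_shifts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("TiltSeries.images must be a (n, ny, nx) stack")
        if len(self.angles) != len(self.images):
            raise ValueError("one tilt angle per image required")
        if len(self.angles) > 1 and not np.all(np.diff(self.angles) > 0):
            raise ValueError("tilt angles must be strictly ascending")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.applied_shifts is not None:
            self.applied_shifts = np.asarray(self.applied_shifts, dtype=float)
            if self.applied_shifts.shape != (len(self.images), 2):
                raise ValueError("applied_shifts must be one (dy, dx) per image")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def zero_tilt_index(self) -> int:
        """Index of the image with minimal absolute tilt angle."""
        return int(np.argmin(np.abs(self.angles)))

    def copy(self) -> "TiltSeries":
        return TiltSeries(
            self.images.copy(),
            self.angles.copy(),
            self.pixel_size,
            self.tilt_axis_rotation,
            self.tilt_axis_offset,
            None if self.applied_shifts is None else self.applied_shifts.copy(),
        )
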