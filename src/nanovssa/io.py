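"""Standard-format I/O: MRC2014 volumes and stacks, JSON sidecars, meshes.

Volumes and tilt stacks are exchanged as MRC2014 mode-2 (float32) files;
the implementation here is a compact reader/writer for exactly that
dialect (x fastest axis, cell dimensions in Angstrom, origin honoured).
Tilt metadata — angles, pixel size, tilt-axis parameters, applied shifts —
lives in a JSON sidecar next to the stack rather than the MRC extended
header: simpler and free of vendor dialects.  Meshes are written as binary
STL or PLY via trimesh; tabular metrics as CSV.
"""
from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from .core import TiltSeries, Volume3D

__all__ = [
    "read_mrc", "write_mrc",
    "read_volume", "write_volume",
    "read_tilt_series", "write_tilt_series",
    "write_mesh",
]

_HEADER_BYTES = 1024
_MODE_FLOAT32 = 2
#: sidecar keys required to reconstruct a TiltSeries
SIDECAR_KEYS = ("angles_deg", "pixel_size_nm", "tilt_axis")


def write_mrc(path, data: np.ndarray, voxel_size_nm: float,
              origin_nm=(0.0, 0.0, 0.0)) -> None:
    """Write a (nz, ny, nx) float array as MRC2014 mode 2."""
    data = np.asarray(data, dtype="<f4")
    if data.ndim != 3:
        raise ValueError("MRC writer expects a 3D array (stack or volume)")
    nz, ny, nx = data.shape
    apix = voxel_size_nm * 10.0  # nm -> Angstrom
    header = bytearray(_HEADER_BYTES)
    struct.pack_into("<10i", header, 0, nx, ny, nz, _MODE_FLOAT32,
                     0, 0, 0, nx, ny, nz)
    struct.pack_into("<6f", header, 40, nx * apix, ny * apix, nz * apix,
                     90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    oz, oy, ox = (float(v) * 10.0 for v in origin_nm)
    struct.pack_into("<3f", header, 196, ox, oy, oz)  # origin, x y z order
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian machst
    struct.pack_into("<f", header, 216, float(data.std()))
    path = Path(path)
    with path.open("wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def read_mrc(path):
    """Read an MRC file; returns (data (nz, ny, nx), voxel_size_nm, origin_nm).

    Only mode 2 (float32) is accepted; other modes and truncated files are
    rejected outright rather than partially read.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_BYTES:
        raise ValueError(f"{path}: truncated MRC file (header incomplete)")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    if mode != _MODE_FLOAT32:
        raise ValueError(f"{path}: unsupported MRC mode {mode} (only mode 2 "
                         "float32 is handled)")
    mx = struct.unpack_from("<i", raw, 28)[0] or nx
    cella_x = struct.unpack_from("<f", raw, 40)[0]
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    expected = _HEADER_BYTES + nsymbt + 4 * nx * ny * nz
    if len(raw) < expected:
        raise ValueError(f"{path}: truncated MRC file "
                         f"({len(raw)} bytes, expected {expected})")
    voxel_nm = (cella_x / mx / 10.0) if cella_x > 0 else 1.0
    ox, oy, oz = struct.unpack_from("<3f", raw, 196)
    data = np.frombuffer(raw, dtype="<f4", count=nx * ny * nz,
                         offset=_HEADER_BYTES + nsymbt).reshape(nz, ny, nx)
    return data.copy(), voxel_nm, np.array([oz, oy, ox]) / 10.0


def write_volume(path, vol: Volume3D) -> None:
    write_mrc(path, vol.values, vol.voxel_size, vol.origin)


def read_volume(path) -> Volume3D:
    data, voxel, origin = read_mrc(path)
    return Volume3D(data, voxel, origin)


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_tilt_series(path, ts: TiltSeries) -> None:
    """MRC stack ordered by angle plus a JSON sidecar with the metadata."""
    write_mrc(path, ts.images, ts.pixel_size)
    meta = {
        "angles_deg": ts.angles.tolist(),
        "pixel_size_nm": ts.pixel_size,
        "tilt_axis": {"rotation_deg": ts.tilt_axis_rotation,
                      "offset_px": ts.tilt_axis_offset},
        "applied_shifts": None if ts.applied_shifts is None
        else ts.applied_shifts.tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_tilt_series(path) -> TiltSeries:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(
            f"missing tilt-series sidecar {sidecar}; expected a JSON file "
            f"with keys {list(SIDECAR_KEYS)}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in SIDECAR_KEYS if k not in meta]
    if missing:
        raise ValueError(f"{sidecar}: sidecar missing keys {missing}")
    data, _voxel, _origin = read_mrc(path)
    shifts = meta.get("applied_shifts")
    return TiltSeries(
        data, np.asarray(meta["angles_deg"], dtype=float),
        pixel_size=float(meta["pixel_size_nm"]),
        tilt_axis_rotation=float(meta["tilt_axis"].get("rotation_deg", 0.0)),
        tilt_axis_offset=float(meta["tilt_axis"].get("offset_px", 0.0)),
        applied_shifts=None if shifts is None else np.asarray(shifts),
    )


def write_mesh(path, mesh) -> None:
    """Export a SurfaceMesh as STL or PLY (by extension) via trimesh."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))
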