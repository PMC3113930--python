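"""Voxel phantoms of gold and silica nanoparticles with known ground truth.

Three particle classes mirror the specimens this pipeline is designed for:

* ``sphere`` — colloidal gold, ~20 nm diameter, the validation control;
* ``branched`` — gold particles ~50 nm across characterised by surface
  extensions, modelled as a core sphere plus capsule-shaped spikes;
* ``aggregate`` — silica-like aggregates of interconnected spherical
  subunits (8–20 nm) grown by a seeded random walk with overlapping necks.

Each phantom carries a :class:`GroundTruth`: analytic closed forms for
spheres, and for the other classes an isosurface-metrology oracle evaluated
on a 4x-finer voxelisation of the same implicit geometry, so that truth and
pipeline measurement never share a code path at the same resolution.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Volume3D
from . import surface as _surface

__all__ = [
    "ParticleSpec",
    "GroundTruth",
    "make_sphere_phantom",
    "make_branched_phantom",
    "make_aggregate_phantom",
    "rasterize_field",
    "reference_metrics",
]


@dataclass
class ParticleSpec:
    """Declarative description of one phantom particle (all lengths nm)."""

    kind: str  # sphere | branched | aggregate
    center: np.ndarray | None = None  # (z, y, x) nm; None = place me
    diameter: float = 20.0            # core / subunit-independent diameter
    n_spikes: int = 0
    spike_length: float = 10.0
    spike_radius: float = 3.0
    n_subunits: int = 1
    subunit_diameter_range: tuple[float, float] = (20.0, 20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "branched", "aggregate"):
            raise ValueError(f"unknown particle kind {self.kind!r}")
        if not self.diameter > 0:
            raise ValueError("diameter must be > 0")
        if self.n_spikes < 0:
            raise ValueError("n_spikes must be >= 0")
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")
        lo, hi = self.subunit_diameter_range
        if lo > hi or lo <= 0:
            raise ValueError("subunit_diameter_range must satisfy 0 < low <= high")
        if self.center is not None:
            self.center = np.asarray(self.center, dtype=float)


@dataclass
class GroundTruth:
    """Reference geometry of one phantom particle."""

    area: float            # nm^2
    volume: float          # nm^3
    vssa: float            # m^2/cm^3
    provenance: str        # analytic | oracle
    true_shifts: np.ndarray | None = None  # filled by the acquisition stage

    def __post_init__(self) -> None:
        if not (self.area > 0 and self.volume > 0):
            raise ValueError("ground-truth area and volume must be > 0")
        if self.provenance not in ("analytic", "oracle"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


# ---------------------------------------------------------------------------
# Implicit geometry: particles are unions of primitives described by signed
# distance functions (negative inside).


def _sphere_prim(center, radius):
    return ("sphere", np.asarray(center, float), float(radius))


def _capsule_prim(a, b, radius):
    return ("capsule", np.asarray(a, float), np.asarray(b, float), float(radius))


def _eval_sdf(primitives, z, y, x):
    """Union signed distance at points (z, y, x); arrays broadcast."""
    d = None
    for prim in primitives:
        if prim[0] == "sphere":
            _, c, r = prim
            di = np.sqrt((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2) - r
        else:
            _, a, b, r = prim
            ab = b - a
            denom = float(ab @ ab)
            pz, py, px = z - a[0], y - a[1], x - a[2]
            t = (pz * ab[0] + py * ab[1] + px * ab[2]) / denom if denom > 0 else 0.0
            t = np.clip(t, 0.0, 1.0)
            di = np.sqrt((pz - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2
                         + (px - t * ab[2]) ** 2) - r
        d = di if d is None else np.minimum(d, di)
    return d


def _rasterize(primitives, voxel_size, grid_shape, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Anti-aliased occupancy grid: interior 1, 3x3x3 subvoxel fractions at
    the boundary band."""
    h = float(voxel_size)
    nz, ny, nx = grid_shape
    oz, oy, ox = origin
    zz = oz + np.arange(nz, dtype=np.float32) * h
    yy = oy + np.arange(ny, dtype=np.float32) * h
    xx = ox + np.arange(nx, dtype=np.float32) * h
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    d = _eval_sdf(primitives, Z, Y, X)
    vals = (d <= 0).astype(np.float32)
    band = np.abs(d) <= h  # only boundary voxels need subsampling
    if np.any(band):
        bz, by, bx = Z[band], Y[band], X[band]
        offs = np.array([-h / 3, 0.0, h / 3], dtype=np.float32)
        inside = np.zeros(bz.shape, dtype=np.float32)
        for dz in offs:
            for dy in offs:
                for dx in offs:
                    inside += (_eval_sdf(primitives, bz + dz, by + dy, bx + dx) <= 0)
        vals[band] = inside / 27.0
    return vals


def _oracle_truth(primitives, voxel_size: float, refine: int = 4) -> GroundTruth:
    """Isosurface metrology of the implicit geometry on a ``refine``-times
    finer grid, via the surface module."""
    h = voxel_size / refine
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for prim in primitives:
        if prim[0] == "sphere":
            _, c, r = prim
            lo = np.minimum(lo, c - r)
            hi = np.maximum(hi, c + r)
        else:
            _, a, b, r = prim
            lo = np.minimum(lo, np.minimum(a, b) - r)
            hi = np.maximum(hi, np.maximum(a, b) + r)
    lo -= 3 * h
    hi += 3 * h
    shape = tuple(int(math.ceil((hi[i] - lo[i]) / h)) + 1 for i in range(3))
    # Signed distance sampled in z slabs to bound memory on fine grids.
    yy = (lo[1] + np.arange(shape[1], dtype=np.float32) * h)[None, :, None]
    xx = (lo[2] + np.arange(shape[2], dtype=np.float32) * h)[None, None, :]
    d = np.empty(shape, dtype=np.float32)
    for z0 in range(0, shape[0], 32):
        z1 = min(z0 + 32, shape[0])
        zz = (lo[0] + np.arange(z0, z1, dtype=np.float32) * h)[:, None, None]
        d[z0:z1] = _eval_sdf(primitives, zz, yy, xx)
    vol = Volume3D(-d, h, origin=lo)
    mesh = _surface.isosurface(vol, 0.0)
    area = _surface.mesh_area(mesh)
    volume = _surface.mesh_volume(mesh)
    return GroundTruth(area, volume, area / volume * _surface.VSSA_FACTOR,
                       provenance="oracle")


def _check_fits(primitives, voxel_size, grid_shape, what: str) -> None:
    h = float(voxel_size)
    extent = np.array([(s - 1) * h for s in grid_shape])
    for prim in primitives:
        pts = [prim[1]] if prim[0] == "sphere" else [prim[1], prim[2]]
        r = prim[-1]
        for p in pts:
            if np.any(p - r < 2 * h) or np.any(p + r > extent - 2 * h):
                raise ValueError(
                    f"{what} does not fit inside the grid with a 2-voxel margin "
                    f"(extent {extent} nm at voxel {h} nm)")


def _require_voxel(voxel_size: float) -> None:
    if not voxel_size > 0:
        raise ValueError(f"voxel_size must be > 0, got {voxel_size}")


def _default_center(grid_shape, voxel_size):
    return np.array([(s - 1) / 2.0 * voxel_size for s in grid_shape])


# ---------------------------------------------------------------------------
# Geometry builders per particle class.


def _sphere_geometry(spec: ParticleSpec, center) -> list:
    return [_sphere_prim(center, spec.diameter / 2.0)]


def _branched_geometry(spec: ParticleSpec, center) -> list:
    if spec.n_spikes > 0 and (spec.spike_length <= 0 or spec.spike_radius <= 0):
        raise ValueError("spike_length and spike_radius must be > 0")
    r_core = spec.diameter / 2.0
    prims = [_sphere_prim(center, r_core)]
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.n_spikes):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        # Capsule from the core centre out to the spike tip; the hemispherical
        # cap ends spike_length beyond the core surface.
        tip = center + v * (r_core + spec.spike_length - spec.spike_radius)
        prims.append(_capsule_prim(center, tip, spec.spike_radius))
    return prims


def _aggregate_geometry(spec: ParticleSpec, center, voxel_size, grid_shape) -> list:
    """Random-walk growth: each new subunit attaches to a randomly chosen
    existing one at centre distance 0.8 x (sum of radii)."""
    lo_d, hi_d = spec.subunit_diameter_range
    h = float(voxel_size)
    extent = np.array([(s - 1) * h for s in grid_shape])
    for attempt in range(10):
        rng = np.random.default_rng(spec.seed + 9973 * attempt)
        subs = [(np.asarray(center, float), rng.uniform(lo_d, hi_d) / 2.0)]
        ok = True
        for _ in range(spec.n_subunits - 1):
            placed = False
            for _try in range(50):
                pc, pr = subs[rng.integers(len(subs))]
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                r_new = rng.uniform(lo_d, hi_d) / 2.0
                c_new = pc + v * 0.8 * (pr + r_new)
                if np.all(c_new - r_new >= 2 * h) and np.all(c_new + r_new <= extent - 2 * h):
                    subs.append((c_new, r_new))
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return [_sphere_prim(c, r) for c, r in subs]
    raise ValueError("aggregate repeatedly grew outside the grid; "
                     "enlarge the grid or reduce n_subunits")


def _build_geometry(spec: ParticleSpec, center, voxel_size, grid_shape) -> list:
    if spec.kind == "sphere" or (spec.kind == "branched" and spec.n_spikes == 0) \
            or (spec.kind == "aggregate" and spec.n_subunits == 1
                and spec.subunit_diameter_range[0] == spec.subunit_diameter_range[1]):
        d = spec.diameter if spec.kind != "aggregate" else spec.subunit_diameter_range[0]
        return [_sphere_prim(center, d / 2.0)]
    if spec.kind == "branched":
        return _branched_geometry(spec, center)
    return _aggregate_geometry(spec, center, voxel_size, grid_shape)


def _truth_for(spec: ParticleSpec, primitives, voxel_size: float) -> GroundTruth:
    if len(primitives) == 1 and primitives[0][0] == "sphere":
        r = primitives[0][2]
        area = 4.0 * math.pi * r ** 2
        volume = 4.0 / 3.0 * math.pi * r ** 3
        return GroundTruth(area, volume, area / volume * _surface.VSSA_FACTOR,
                           provenance="analytic")
    return _oracle_truth(primitives, voxel_size)


def _make_phantom(spec, voxel_size, grid_shape, expected_kind):
    _require_voxel(voxel_size)
    if spec.kind != expected_kind:
        raise ValueError(f"expected a {expected_kind!r} spec, got {spec.kind!r}")
    center = spec.center if spec.center is not None \
        else _default_center(grid_shape, voxel_size)
    prims = _build_geometry(spec, center, voxel_size, grid_shape)
    _check_fits(prims, voxel_size, grid_shape, f"{spec.kind} phantom")
    vol = Volume3D(_rasterize(prims, voxel_size, grid_shape), voxel_size)
    return vol, _truth_for(spec, prims, voxel_size)


def make_sphere_phantom(spec: ParticleSpec, voxel_size: float, grid_shape):
    """Rasterise a single spherical particle; truth is 4 pi r^2, 4/3 pi r^3."""
    return _make_phantom(spec, voxel_size, grid_shape, "sphere")


def make_branched_phantom(spec: ParticleSpec, voxel_size: float, grid_shape):
    """Core sphere plus seeded capsule spikes; truth from the fine-grid oracle."""
    return _make_phantom(spec, voxel_size, grid_shape, "branched")


def make_aggregate_phantom(spec: ParticleSpec, voxel_size: float, grid_shape):
    """Connected aggregate of overlapping spherical subunits (silica-like)."""
    return _make_phantom(spec, voxel_size, grid_shape, "aggregate")


# ---------------------------------------------------------------------------


def _extent_radius(prims, center) -> float:
    r = 0.0
    for prim in prims:
        pts = [prim[1]] if prim[0] == "sphere" else [prim[1], prim[2]]
        for p in pts:
            r = max(r, float(np.linalg.norm(p - center)) + prim[-1])
    return r


def rasterize_field(specs, voxel_size: float, grid_shape, min_separation: float,
                    seed: int = 0, max_attempts: int = 200,
                    placement: str = "monolayer", z_spread: float = 4.0,):
    """Place several particles in one volume with pairwise surface separation
    >= ``min_separation`` and rasterise their union.

    Specs without an explicit centre are placed at random (seeded) inside
    the cylinder about the tilt (y) axis that stays within the projection
    field of view at all tilt angles, so simulated tilt series of the field
    conserve mass.  The default ``monolayer`` placement emulates particles
    dispersed on a support film: centres lie within ``z_spread`` nm of the
    central plane and, where the packing allows, separation is enforced in
    the beam-projected (y, x) plane as well, so zero-tilt projections of
    sparse fields show discrete particles as real grid preparations do.
    ``placement="volume"`` distributes centres uniformly in the cylinder
    with 3D separation only.  Returns the volume and per-particle truths in
    placement order.
    """
    if placement not in ("monolayer", "volume"):
        raise ValueError(f"unknown placement mode {placement!r}")
    _require_voxel(voxel_size)
    if len(specs) < 1:
        raise ValueError("at least one particle spec required")
    h = float(voxel_size)
    nz, ny, nx = grid_shape
    extent = np.array([(s - 1) * h for s in grid_shape])
    cz, cx = extent[0] / 2.0, extent[2] / 2.0
    # margin absorbs residual jitter offset, reconstruction blur and streaks
    # so segmented particles stay clear of the volume border
    r_cyl = min(cz, cx) - 6 * h
    rng = np.random.default_rng(seed)

    placed: list[tuple[np.ndarray, float]] = []  # (center, extent radius)
    all_prims: list[list] = []
    truths: list[GroundTruth] = []
    for i, spec in enumerate(specs):
        # Extent radius needs trial geometry; for random placement the
        # geometry is rebuilt at the final centre (aggregates are grown in
        # place so their footprint respects the grid).
        probe_center = spec.center if spec.center is not None else extent / 2.0
        r_ext = _extent_radius(
            _build_geometry(spec, probe_center, voxel_size, grid_shape), probe_center)
        y_lo, y_hi = r_ext + 9 * h, extent[1] - r_ext - 9 * h
        if y_lo > y_hi or r_ext >= r_cyl:
            raise ValueError(f"particle {i} ({spec.kind}) too large for the grid")
        center = None
        if spec.center is not None:
            cand = np.asarray(spec.center, float)
            if not all(np.linalg.norm(cand - pc) - r_ext - pr >= min_separation
                       for pc, pr in placed):
                raise ValueError(
                    f"particle {i} ({spec.kind}) at its fixed centre violates "
                    f"min_separation {min_separation} nm")
            center = cand
        best_depth_cand = None  # (min projected sep, candidate)
        for _attempt in range(max_attempts if center is None else 0):
            flat = placement == "monolayer" and _attempt < max_attempts * 4 // 5
            if flat:
                dz = rng.uniform(-min(z_spread, r_cyl - r_ext),
                                 min(z_spread, r_cyl - r_ext))
                xr = math.sqrt(max((r_cyl - r_ext) ** 2 - dz ** 2, 0.0))
                cand = np.array([cz + dz,
                                 rng.uniform(y_lo, y_hi),
                                 cx + rng.uniform(-xr, xr)])
            else:
                # uniform in the allowed disc x uniform in y
                rad = (r_cyl - r_ext) * math.sqrt(rng.uniform())
                phi = rng.uniform(0, 2 * math.pi)
                cand = np.array([cz + rad * math.cos(phi),
                                 rng.uniform(y_lo, y_hi),
                                 cx + rad * math.sin(phi)])
            # a monolayer keeps particles separated in projection too; once
            # the packing is too tight for that, stack in depth with 3D
            # separation only (projected superposition then possible)
            if flat:
                sep_ok = all(
                    np.linalg.norm(cand[1:] - pc[1:]) - r_ext - pr >= min_separation
                    for pc, pr in placed)
                if sep_ok:
                    center = cand
                    break
            else:
                sep_ok = all(
                    np.linalg.norm(cand - pc) - r_ext - pr >= min_separation
                    for pc, pr in placed)
                if sep_ok:
                    # depth-stacked candidates are all 3D-valid; keep the one
                    # whose zero-tilt projection overlaps least
                    proj_sep = min((np.linalg.norm(cand[1:] - pc[1:]) - r_ext - pr
                                    for pc, pr in placed), default=np.inf)
                    if best_depth_cand is None or proj_sep > best_depth_cand[0]:
                        best_depth_cand = (proj_sep, cand)
                    if proj_sep >= min_separation or placement == "volume":
                        center = cand
                        break
        if center is None and best_depth_cand is not None:
            center = best_depth_cand[1]
        if center is None:
            raise ValueError(
                f"could not place particle {i} ({spec.kind}) after "
                f"{max_attempts} attempts; reduce particle count or separation")
        prims = _build_geometry(spec, center, voxel_size, grid_shape)
        _check_fits(prims, voxel_size, grid_shape, f"particle {i} ({spec.kind})")
        placed.append((center, _extent_radius(prims, center)))
        all_prims.append(prims)
        truths.append(_truth_for(spec, prims, voxel_size))

    flat = [p for prims in all_prims for p in prims]
    vol = Volume3D(_rasterize(flat, voxel_size, grid_shape), voxel_size)
    return vol, truths


@dataclass
class FieldMetrics:
    """Aggregate reference totals over a list of particle truths."""

    total_area: float    # nm^2
    total_volume: float  # nm^3
    vssa: float          # m^2/cm^3


def reference_metrics(truths) -> FieldMetrics:
    """Sum per-particle truth areas/volumes; aggregate VSSA of the field."""
    if not truths:
        raise ValueError("reference_metrics requires a non-empty truth list")
    a = float(sum(t.area for t in truths))
    v = float(sum(t.volume for t in truths))
    return FieldMetrics(a, v, a / v * _surface.VSSA_FACTOR)
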