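import numpy as np
import pytest

import nanovssa as nv


@pytest.fixture(scope="session")
def sphere64():
    """Centred 20 nm sphere phantom in a 64^3 grid at 1 nm voxels."""
    spec = nv.ParticleSpec("sphere", diameter=20.0)
    vol, truth = nv.make_sphere_phantom(spec, 1.0, (64, 64, 64))
    return vol, truth


@pytest.fixture(scope="session")
def ts_full(sphere64):
    """Noise-free full-range (+/-90 deg, 2 deg steps) series of the sphere."""
    vol, _ = sphere64
    params = nv.AcquisitionParams(tilt_min=-90, tilt_max=88, increment=2)
    return nv.project_series(vol, params)


@pytest.fixture(scope="session")
def ts_wedge(sphere64):
    """Noise-free +/-65 deg, 2 deg series (missing-wedge benchmark)."""
    vol, _ = sphere64
    params = nv.AcquisitionParams(tilt_min=-64, tilt_max=64, increment=2)
    return nv.project_series(vol, params)


@pytest.fixture(scope="session")
def ball_mask():
    """Hard binary ball of radius 10 voxels (1 nm) with 3 voxels padding."""
    n = 27
    c = (n - 1) / 2.0
    zz, yy, xx = np.mgrid[:n, :n, :n]
    r = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
    return nv.Volume3D((r <= 10).astype(np.float32), 1.0)
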