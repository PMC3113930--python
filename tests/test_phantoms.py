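"""Phantom generation: geometry, ground truth and placement."""
import math

import numpy as np
import pytest
from scipy import ndimage

import nanovssa as nv
from nanovssa.phantoms import FieldMetrics

SPHERE_AREA_20NM = 4 * math.pi * 100      # 1256.637 nm^2
SPHERE_VOL_20NM = 4 / 3 * math.pi * 1000  # 4188.790 nm^3


class TestSpherePhantom:
    def test_analytic_truth_closed_forms(self):
        spec = nv.ParticleSpec("sphere", diameter=20.0)
        _, truth = nv.make_sphere_phantom(spec, 0.5, (64, 64, 64))
        assert truth.area == pytest.approx(1256.64, abs=0.01)
        assert truth.volume == pytest.approx(4188.79, abs=0.01)
        assert truth.vssa == pytest.approx(300.0, abs=1e-9)
        assert truth.provenance == "analytic"

    def test_voxel_count_volume_matches_closed_form(self):
        spec = nv.ParticleSpec("sphere", diameter=20.0)
        vol, truth = nv.make_sphere_phantom(spec, 0.5, (64, 64, 64))
        voxel_vol = float(vol.values.sum()) * 0.5 ** 3
        assert voxel_vol == pytest.approx(truth.volume, rel=0.02)

    def test_volume_error_shrinks_with_voxel_size(self):
        # discretisation error of the binarised mask halves (at least) when
        # the voxel size halves, for radii >= 8 voxels
        spec = nv.ParticleSpec("sphere", diameter=20.0)
        errs = []
        for h, n in [(1.0, 32), (0.5, 64)]:
            vol, truth = nv.make_sphere_phantom(spec, h, (n, n, n))
            mask_vol = float((vol.values >= 0.5).sum()) * h ** 3
            errs.append(abs(mask_vol - truth.volume) / truth.volume)
        assert errs[1] < errs[0] / 2
        assert errs[1] < 0.01

    def test_rejects_sphere_larger_than_grid(self):
        spec = nv.ParticleSpec("sphere", diameter=40.0)
        with pytest.raises(ValueError, match="fit"):
            nv.make_sphere_phantom(spec, 1.0, (32, 32, 32))

    def test_rejects_nonpositive_voxel(self):
        spec = nv.ParticleSpec("sphere", diameter=20.0)
        with pytest.raises(ValueError, match="voxel_size"):
            nv.make_sphere_phantom(spec, 0.0, (64, 64, 64))


class TestBranchedPhantom:
    def test_zero_spikes_degenerates_to_sphere(self):
        b = nv.ParticleSpec("branched", diameter=20.0, n_spikes=0)
        s = nv.ParticleSpec("sphere", diameter=20.0)
        vb, tb = nv.make_branched_phantom(b, 1.0, (48, 48, 48))
        vs, ts = nv.make_sphere_phantom(s, 1.0, (48, 48, 48))
        assert np.array_equal(vb.values, vs.values)
        assert tb.area == pytest.approx(ts.area)

    def test_seeded_generation_bit_reproducible(self):
        spec = nv.ParticleSpec("branched", diameter=30.0, n_spikes=6,
                               spike_length=8.0, spike_radius=3.0, seed=7)
        v1, _ = nv.make_branched_phantom(spec, 1.0, (64, 64, 64))
        v2, _ = nv.make_branched_phantom(spec, 1.0, (64, 64, 64))
        assert np.array_equal(v1.values, v2.values)

    def test_spikes_raise_vssa_above_bare_core(self):
        # a 30 nm core alone has VSSA 6/d = 200; spikes add relatively
        # more area than volume
        spec = nv.ParticleSpec("branched", diameter=30.0, n_spikes=12,
                               spike_length=10.0, spike_radius=3.0, seed=7)
        _, truth = nv.make_branched_phantom(spec, 1.0, (64, 64, 64))
        assert truth.provenance == "oracle"
        assert truth.vssa > 200.0

    def test_rejects_degenerate_spikes(self):
        spec = nv.ParticleSpec("branched", diameter=30.0, n_spikes=3,
                               spike_length=5.0, spike_radius=3.0)
        spec.spike_radius = -1.0
        with pytest.raises(ValueError, match="spike"):
            nv.make_branched_phantom(spec, 1.0, (64, 64, 64))


class TestAggregatePhantom:
    def test_single_subunit_is_a_sphere(self):
        a = nv.ParticleSpec("aggregate", n_subunits=1,
                            subunit_diameter_range=(20.0, 20.0))
        va, ta = nv.make_aggregate_phantom(a, 1.0, (48, 48, 48))
        s = nv.ParticleSpec("sphere", diameter=20.0)
        vs, _ = nv.make_sphere_phantom(s, 1.0, (48, 48, 48))
        assert np.array_equal(va.values, vs.values)
        assert ta.vssa == pytest.approx(300.0, rel=1e-6)

    def test_aggregate_is_single_connected_component(self):
        spec = nv.ParticleSpec("aggregate", n_subunits=15,
                               subunit_diameter_range=(20.0, 20.0), seed=3)
        vol, truth = nv.make_aggregate_phantom(spec, 1.0, (96, 96, 96))
        _, n = ndimage.label(vol.values >= 0.5, structure=np.ones((3, 3, 3)))
        assert n == 1
        # necks remove surface relative to isolated 20 nm spheres (6/d = 300)
        assert 0 < truth.vssa < 300.0


class TestRasterizeField:
    def test_single_fixed_sphere_matches_make_sphere(self):
        center = (31.5, 31.5, 31.5)
        spec = nv.ParticleSpec("sphere", center=center, diameter=20.0)
        vf, truths = nv.rasterize_field([spec], 1.0, (64, 64, 64), 5.0)
        vs, ts = nv.make_sphere_phantom(
            nv.ParticleSpec("sphere", center=center, diameter=20.0), 1.0,
            (64, 64, 64))
        assert np.array_equal(vf.values, vs.values)
        assert truths[0].volume == pytest.approx(ts.volume)

    def test_eleven_spheres_give_eleven_components(self):
        specs = [nv.ParticleSpec("sphere", diameter=20.0) for _ in range(11)]
        vol, truths = nv.rasterize_field(specs, 1.0, (96, 96, 96), 5.0, seed=4)
        _, n = ndimage.label(vol.values >= 0.5, structure=np.ones((3, 3, 3)))
        assert n == 11
        assert len(truths) == 11

    def test_total_truth_volume_is_additive(self):
        specs = [nv.ParticleSpec("sphere", diameter=20.0) for _ in range(4)]
        _, truths = nv.rasterize_field(specs, 1.0, (96, 96, 96), 5.0, seed=1)
        total = nv.reference_metrics(truths).total_volume
        assert total == pytest.approx(sum(t.volume for t in truths))
        assert total == pytest.approx(4 * SPHERE_VOL_20NM, rel=1e-6)

    def test_impossible_packing_is_rejected_with_culprit(self):
        specs = [nv.ParticleSpec("sphere", diameter=20.0) for _ in range(30)]
        with pytest.raises(ValueError, match="particle"):
            nv.rasterize_field(specs, 1.0, (64, 64, 64), 5.0, seed=0)


class TestReferenceMetrics:
    def test_two_spheres_totals(self):
        t = nv.make_sphere_phantom(
            nv.ParticleSpec("sphere", diameter=20.0), 1.0, (48, 48, 48))[1]
        m = nv.reference_metrics([t, t])
        assert m.total_volume == pytest.approx(8377.58, abs=0.01)
        assert m.vssa == pytest.approx(300.0)

    def test_single_particle_is_identity(self):
        t = nv.make_sphere_phantom(
            nv.ParticleSpec("sphere", diameter=20.0), 1.0, (48, 48, 48))[1]
        m = nv.reference_metrics([t])
        assert (m.total_area, m.total_volume, m.vssa) == \
            pytest.approx((t.area, t.volume, t.vssa))

    def test_mixed_sizes_vssa_between_extremes(self):
        t10 = nv.make_sphere_phantom(
            nv.ParticleSpec("sphere", diameter=10.0), 0.5, (48, 48, 48))[1]
        t20 = nv.make_sphere_phantom(
            nv.ParticleSpec("sphere", diameter=20.0), 1.0, (48, 48, 48))[1]
        m = nv.reference_metrics([t10, t20])
        assert 300.0 < m.vssa < 600.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            nv.reference_metrics([])


def test_truth_vssa_positive_and_finite_for_all_classes():
    cases = [
        nv.make_sphere_phantom(
            nv.ParticleSpec("sphere", diameter=20.0), 1.0, (48, 48, 48)),
        nv.make_branched_phantom(
            nv.ParticleSpec("branched", diameter=24.0, n_spikes=4,
                            spike_length=6.0, spike_radius=2.5, seed=1),
            1.0, (48, 48, 48)),
        nv.make_aggregate_phantom(
            nv.ParticleSpec("aggregate", n_subunits=5,
                            subunit_diameter_range=(10.0, 14.0), seed=2),
            1.0, (64, 64, 64)),
    ]
    for _, truth in cases:
        assert np.isfinite(truth.vssa) and truth.vssa > 0
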