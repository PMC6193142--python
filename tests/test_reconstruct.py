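import numpy as np
import pytest

from fibrilscope import _geometry
from fibrilscope.core import AlignmentRecord, ParticleStack, Volume3D
from fibrilscope import reconstruct as R
from fibrilscope.phantoms import make_tilt_series


def soft_sphere(n=48, radius=16.0, edge=2.0, voxel=8.0):
    c = (n - 1) / 2
    zz, yy, xx = np.mgrid[:n, :n, :n]
    r = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
    return Volume3D(np.clip((radius - r) / edge, 0, 1), voxel), r


class TestProjection:
    def test_azimuth_0_and_360_identical(self, default_phantom):
        p0 = R.project_about_axis(default_phantom, 0.0)
        p360 = R.project_about_axis(default_phantom, 360.0)
        assert np.array_equal(p0, p360)

    def test_c2_phantom_projections_repeat_every_180(self, default_phantom):
        p0 = R.project_about_axis(default_phantom, 33.0)
        p180 = R.project_about_axis(default_phantom, 213.0)
        rel = np.abs(p0 - p180).max() / np.abs(p0).max()
        assert rel < 1e-3

    def test_ball_projection_matches_chord_length_integral(self):
        n, radius = 64, 20.0
        c = (n - 1) / 2
        zz, yy, xx = np.mgrid[:n, :n, :n]
        r3 = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
        ball = Volume3D((r3 < radius).astype(float), 8.0)
        proj = R.project_about_axis(ball, 33.0)
        d = np.hypot((np.arange(n) - c)[:, None] * 0 + (np.arange(n) - c)[None, :],
                     (np.arange(n) - c)[:, None])
        analytic = 2 * np.sqrt(np.clip(radius ** 2 - d ** 2, 0, None))
        rms = np.sqrt(((proj - analytic) ** 2).mean())
        assert rms / np.sqrt((analytic ** 2).mean()) < 0.02


class TestWBPFilament:
    def test_round_trip_correlation_above_095(self, default_phantom):
        phis = np.arange(0, 360, 5.0)
        images = np.stack([R.project_about_axis(default_phantom, p) for p in phis])
        stack = ParticleStack(images.astype(np.float32), 8.0)
        records = [AlignmentRecord(phi=p) for p in phis]
        rec = R.wbp_filament(stack, records, 8.0)
        n = default_phantom.shape[1]
        c = (n - 1) / 2
        yy, xx = np.mgrid[:n, :n]
        mask = np.broadcast_to((yy - c) ** 2 + (xx - c) ** 2 < (n // 4) ** 2,
                               default_phantom.shape)
        corr = np.corrcoef(rec.data[mask], default_phantom.data[mask])[0, 1]
        assert corr > 0.95

    def test_zero_stack_gives_zero_volume(self):
        stack = ParticleStack(np.zeros((5, 16, 16), np.float32), 8.0)
        records = [AlignmentRecord(phi=p) for p in (0, 40, 80, 120, 160)]
        assert np.abs(R.wbp_filament(stack, records, 8.0).data).max() < 1e-6

    def test_linearity_doubling_intensities(self, rng):
        data = rng.normal(size=(6, 16, 16)).astype(np.float32)
        records = [AlignmentRecord(phi=30.0 * i) for i in range(6)]
        v1 = R.wbp_filament(ParticleStack(data, 8.0), records, 8.0)
        v2 = R.wbp_filament(ParticleStack(2 * data, 8.0), records, 8.0)
        assert np.allclose(v2.data, 2 * v1.data, atol=1e-4)

    def test_few_azimuths_warns(self, rng):
        data = rng.normal(size=(4, 16, 16)).astype(np.float32)
        records = [AlignmentRecord(phi=0.0) for _ in range(4)]
        with pytest.warns(RuntimeWarning, match="azimuth"):
            R.wbp_filament(ParticleStack(data, 8.0), records, 8.0)


class TestImposeCn:
    def test_n1_is_identity(self, rng):
        vol = Volume3D(rng.normal(size=(16, 16, 16)), 8.0)
        assert np.array_equal(R.impose_cn(vol, 1).data, vol.data)

    def test_c2_twice_equals_once(self, rng):
        vol = Volume3D(rng.normal(size=(16, 16, 16)), 8.0)
        once = R.impose_cn(vol, 2)
        twice = R.impose_cn(once, 2)
        assert np.abs(once.data - twice.data).max() < 1e-6

    def test_c4_output_invariant_under_90_degrees(self, rng):
        vol = Volume3D(rng.normal(size=(16, 16, 16)), 8.0)
        out = R.impose_cn(vol, 4)
        rot = _geometry.rotate_volume_z(out.data, 90.0)
        rel = np.sqrt(((out.data - rot) ** 2).mean() / (out.data ** 2).mean())
        assert rel < 1e-3

    def test_norm_non_increasing(self, rng):
        vol = Volume3D(rng.normal(size=(16, 16, 16)), 8.0)
        for n in (2, 4):
            out = R.impose_cn(vol, n)
            assert np.linalg.norm(out.data) <= np.linalg.norm(vol.data) + 1e-6


class TestCylindricalInitialModel:
    def test_reprojection_matches_cylinder_projection(self, default_phantom):
        phis = np.arange(0, 360, 15.0)
        avg = np.stack([R.project_about_axis(default_phantom, p)
                        for p in phis]).mean(axis=0)
        model = R.cylindrical_initial_model(avg, 8.0)
        reproj = R.project_about_axis(model, 77.0)
        assert np.corrcoef(reproj.ravel(), avg.ravel())[0, 1] > 0.99

    def test_rotating_output_90_gives_identical_volume(self, default_phantom):
        avg = R.project_about_axis(default_phantom, 0.0)
        model = R.cylindrical_initial_model(avg, 8.0)
        rot = _geometry.rotate_volume_z(model.data, 90.0)
        rel = np.sqrt(((model.data - rot) ** 2).mean() / (model.data ** 2).mean())
        assert rel < 1e-3

    def test_zero_input_gives_zero_volume(self):
        model = R.cylindrical_initial_model(np.zeros((32, 32)), 8.0)
        assert np.abs(model.data).max() == 0.0

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            R.cylindrical_initial_model(np.zeros((16, 24)), 8.0)


class TestWBPTilt:
    def test_sphere_round_trip_and_missing_wedge(self):
        sphere, r = soft_sphere()
        inside = r < 24
        partial = R.wbp_tilt(make_tilt_series(sphere, -65, 65, 1))
        full = R.wbp_tilt(make_tilt_series(sphere, -90, 90, 1))
        c_partial = np.corrcoef(partial.data[inside], sphere.data[inside])[0, 1]
        c_full = np.corrcoef(full.data[inside], sphere.data[inside])[0, 1]
        assert c_partial > 0.9
        assert c_full > c_partial  # the missing wedge costs fidelity

    def test_single_tilt_rejected(self):
        sphere, _ = soft_sphere(n=16)
        series = make_tilt_series(sphere, -1, 1, 1)
        series.data = series.data[:1]
        series.angles = series.angles[:1]
        with pytest.raises(ValueError):
            R.wbp_tilt(series)


class TestIsoLevel:
    def test_half_box_target_gives_median_level(self, rng):
        vol = Volume3D(rng.random((16, 16, 16)), 10.0)  # 1 nm voxels
        total_nm3 = 16 ** 3
        level = R.iso_level_for_volume_fraction(vol, 0.5, total_nm3)
        frac_above = (vol.data > level).mean()
        assert frac_above == pytest.approx(0.5, abs=2 / 16 ** 3 * 10)

    def test_larger_fraction_gives_lower_level(self, rng):
        vol = Volume3D(rng.random((12, 12, 12)), 10.0)
        l1 = R.iso_level_for_volume_fraction(vol, 0.2, 500.0)
        l2 = R.iso_level_for_volume_fraction(vol, 0.6, 500.0)
        assert l2 <= l1

    def test_overflowing_target_rejected(self, rng):
        vol = Volume3D(rng.random((8, 8, 8)), 10.0)
        with pytest.raises(ValueError):
            R.iso_level_for_volume_fraction(vol, 1.0, 10 * 8 ** 3)

    def test_bead_core_connected_at_40_percent_of_8_chain_volume(self, default_phantom):
        from scipy import ndimage
        # eight chains of ~350 kDa fibrillin fragments per repeat
        ref_volume = R.mass_to_volume(8 * 350.0)
        level = R.iso_level_for_volume_fraction(default_phantom, 0.40, ref_volume)
        above = default_phantom.data > level
        # restrict to the bead region of the first repeat
        bead = above[: int(0.3 * 74)]
        labels, n_comp = ndimage.label(bead)
        sizes = np.bincount(labels.ravel())[1:]
        assert sizes.max() > 0.9 * bead.sum()


class TestMassVolume:
    def test_2500_kda_is_about_3050_nm3(self):
        assert R.mass_to_volume(2500.0) == pytest.approx(3.05e3, rel=0.02)

    def test_inverse_round_trip(self):
        assert R.volume_to_mass(R.mass_to_volume(1400.0)) == pytest.approx(1400.0)

    def test_non_positive_mass_rejected(self):
        with pytest.raises(ValueError):
            R.mass_to_volume(0.0)


class TestModelMeasurements:
    def test_phantom_periodicity_and_diameter(self, default_phantom):
        assert R.axial_periodicity(default_phantom) == pytest.approx(59.2, rel=0.02)
        assert R.max_diameter_fwhm(default_phantom) == pytest.approx(20.8, rel=0.02)
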