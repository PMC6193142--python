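import numpy as np
import pytest
from scipy.signal import find_peaks

from fibrilscope import _geometry
from fibrilscope.phantoms import (FiberStackSpec, PhantomSpec,
                                  TomogramPhantomSpec, make_fiber_sections,
                                  make_microfibril_phantom,
                                  make_projection_dataset, make_tilt_series,
                                  make_tomogram_phantom)
from fibrilscope.core import Volume3D
from fibrilscope.reconstruct import project_about_axis


class TestMicrofibrilPhantom:
    def test_imposed_c2_is_exact_to_machine_precision(self, default_phantom):
        rotated = _geometry.rotate_volume_z(default_phantom.data, 180.0)
        assert np.array_equal(rotated, default_phantom.data)

    def test_axial_autocorrelation_peak_at_repeat_distance(self):
        # 59.2 nm / 0.8 nm per voxel = 74 voxels on a 128-px box
        vol = make_microfibril_phantom(PhantomSpec(), 128, 8.0)
        prof = vol.data.mean(axis=(1, 2)).astype(float)
        prof -= prof.mean()
        ac = np.correlate(prof, prof, mode="full")[len(prof) - 1:]
        peaks, _ = find_peaks(ac, prominence=0.1 * np.ptp(ac))
        assert peaks[0] == 74

    def test_interbead_is_hollow_on_axis(self, default_phantom):
        # mid-interbead z of the first repeat (frac 0.65 of 74 voxels)
        z = int(0.65 * 59.2 * 10 / 8)
        sl = default_phantom.data[z]
        c = sl.shape[0] // 2
        on_axis = sl[c - 1: c + 1, c - 1: c + 1].mean()
        assert on_axis < 0.5 * sl.max()

    def test_interbead_contains_n_strands(self, default_phantom):
        z = int(0.65 * 59.2 * 10 / 8)
        sl = default_phantom.data[z].astype(float)
        n = sl.shape[0]
        c = (n - 1) / 2
        yy, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
        r = np.hypot(yy, xx)
        ring = np.abs(r - 12.0 * 10 / 2 / 8) < 2
        theta = np.arctan2(yy, xx)[ring]
        vals = sl[ring]
        # dominant angular harmonic of the interbead ring = strand count
        power = [np.abs((vals * np.exp(-1j * k * theta)).sum())
                 for k in range(1, 9)]
        assert np.argmax(power) + 1 == 4

    def test_c8_interbead_self_correlates_every_45_degrees(self, phantom_c8):
        rotated = _geometry.rotate_volume_z(phantom_c8.data, 90.0)
        assert np.allclose(rotated, phantom_c8.data, atol=1e-6)

    def test_box_too_small_rejected(self):
        with pytest.raises(ValueError, match="repeat"):
            make_microfibril_phantom(PhantomSpec(), 64, 8.0)

    def test_chains_must_be_multiple_of_symmetry(self):
        with pytest.raises(ValueError, match="multiple"):
            PhantomSpec(n_chains=6, axial_symmetry_order=4)


class TestProjectionDataset:
    def test_identity_configuration_equals_direct_projection(self, default_phantom):
        stack, recs = make_projection_dataset(default_phantom, 1, snr=np.inf,
                                              shift_max=0.0, seed=0, psi_max=1e-12)
        rec = recs[0]
        expected = project_about_axis(default_phantom, rec.phi)
        assert np.allclose(stack.data[0], expected, atol=1e-4)

    def test_same_seed_gives_bit_identical_stacks(self, default_phantom):
        s1, _ = make_projection_dataset(default_phantom, 10, snr=0.5, seed=7)
        s2, _ = make_projection_dataset(default_phantom, 10, snr=0.5, seed=7)
        assert np.array_equal(s1.data, s2.data)

    def test_snr_one_gives_equal_signal_and_noise_variance(self, default_phantom):
        n = 100
        clean, recs = make_projection_dataset(default_phantom, n, snr=np.inf,
                                              shift_max=4.0, seed=3)
        noisy, _ = make_projection_dataset(default_phantom, n, snr=1.0,
                                           shift_max=4.0, seed=3)
        ratio = []
        for i in range(n):
            sig = clean.data[i].var()
            noise = (noisy.data[i] - clean.data[i]).var()
            ratio.append(sig / noise)
        assert np.mean(ratio) == pytest.approx(1.0, rel=0.1)

    def test_non_positive_snr_rejected(self, default_phantom):
        with pytest.raises(ValueError, match="snr"):
            make_projection_dataset(default_phantom, 1, snr=0.0)


class TestTiltSeries:
    def test_paper_range_gives_131_images(self, rng):
        vol = Volume3D(rng.normal(size=(16, 16, 16)), 8.0)
        series = make_tilt_series(vol, -65, 65, 1)
        assert len(series) == 131
        assert series.angles[0] == -65 and series.angles[-1] == 65

    def test_degenerate_range_rejected(self, rng):
        vol = Volume3D(rng.normal(size=(8, 8, 8)), 8.0)
        with pytest.raises(ValueError, match="empty"):
            make_tilt_series(vol, 0, 0, 1)

    def test_sphere_projections_are_tilt_invariant(self):
        n = 48
        c = (n - 1) / 2
        zz, yy, xx = np.mgrid[:n, :n, :n]
        r = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
        sphere = Volume3D(np.clip((16.0 - r) / 2.0, 0, 1), 8.0)
        series = make_tilt_series(sphere, -60, 60, 20)
        p0 = series.data[len(series) // 2]
        for img in series.data:
            rel = np.sqrt(((img - p0) ** 2).mean()) / np.sqrt((p0 ** 2).mean())
            assert rel < 0.01


class TestTomogramPhantom:
    def test_parallel_zero_dispersion_tangents_all_equal(self):
        spec = TomogramPhantomSpec(n_filaments=10)
        _, traces = make_tomogram_phantom(spec, 120, 1.0, seed=0)
        for t in traces:
            assert np.allclose(t.tangents, [1.0, 0.0, 0.0], atol=1e-9)

    def test_mean_nearest_neighbor_distance_near_default_spacing(self):
        from fibrilscope.morphometry import orientation_and_spacing
        _, traces = make_tomogram_phantom(TomogramPhantomSpec(), 200, 1.0, seed=1)
        _, summary = orientation_and_spacing(traces)
        assert summary["mean_nn_distance_nm"] == pytest.approx(30.0, rel=0.05)

    def test_meshwork_dispersion_matches_target(self):
        from fibrilscope.morphometry import orientation_and_spacing
        spec = TomogramPhantomSpec(orientation_mode="meshwork",
                                   orientation_dispersion=30.0, n_filaments=60)
        _, traces = make_tomogram_phantom(spec, 200, 1.0, seed=2)
        assert len(traces) >= 50
        _, summary = orientation_and_spacing(traces)
        assert 25.0 <= summary["rms_relative_angle_deg"] <= 35.0

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            make_tomogram_phantom(TomogramPhantomSpec(), 40, 1.0, seed=0)

    def test_seed_determinism(self):
        v1, _ = make_tomogram_phantom(TomogramPhantomSpec(n_filaments=8), 120, 1.0, seed=5)
        v2, _ = make_tomogram_phantom(TomogramPhantomSpec(n_filaments=8), 120, 1.0, seed=5)
        assert np.array_equal(v1.data, v2.data)


class TestFiberSections:
    def test_zero_obliquity_gives_circles(self):
        spec = FiberStackSpec(n_fibers=5, n_slices=2, section_obliquity=0.0)
        contours, _ = make_fiber_sections(spec, seed=0, contour_noise=0.0)
        from fibrilscope.morphometry import fit_contour_table
        fits = fit_contour_table(contours, spec.pixel_size)
        assert np.allclose(fits.major_semi_px, fits.minor_semi_px, rtol=1e-6)

    def test_60_degree_obliquity_doubles_major_axis(self):
        spec = FiberStackSpec(n_fibers=5, n_slices=2, section_obliquity=60.0)
        contours, _ = make_fiber_sections(spec, seed=0, contour_noise=0.0)
        from fibrilscope.morphometry import fit_contour_table
        fits = fit_contour_table(contours, spec.pixel_size)
        assert np.allclose(fits.major_semi_px / fits.minor_semi_px, 2.0, rtol=1e-6)

    def test_truth_mean_matches_default_within_100nm(self):
        spec = FiberStackSpec()
        _, truth = make_fiber_sections(spec, seed=3, slices=[0])
        assert truth.diameter_um.mean() == pytest.approx(2.06, abs=0.1)

    def test_obliquity_90_rejected(self):
        with pytest.raises(ValueError):
            FiberStackSpec(section_obliquity=90.0)
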