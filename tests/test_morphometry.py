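import numpy as np
import pandas as pd
import pytest

from fibrilscope.core import FilamentTrace, Volume3D
from fibrilscope import morphometry as M
from fibrilscope.phantoms import TomogramPhantomSpec, make_tomogram_phantom


def straight_tube(n=80, cy=40.0, cx=40.0, sigma=4.84, beading_period=None):
    zz, yy, xx = np.mgrid[:n, :n, :n]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    vol = np.exp(-r2 / (2 * sigma ** 2))
    if beading_period:
        vol = vol * (1.0 + 0.5 * np.cos(2 * np.pi * zz / beading_period))
    return Volume3D(vol.astype(np.float32), 10.0)  # 1 nm voxels


class TestTracing:
    def test_straight_filament_traced_within_one_voxel(self):
        vol = straight_tube()
        traces = M.trace_filaments(vol, [[40.0, 41.0, 39.0]])
        assert len(traces) == 1 and len(traces[0]) > 10
        lateral = traces[0].points[:, 1:] - np.array([40.0, 40.0])
        rms = np.sqrt((lateral ** 2).sum(axis=1).mean())
        assert rms < 1.0

    def test_parallel_filaments_do_not_swap(self):
        n = 80
        zz, yy, xx = np.mgrid[:n, :n, :n]
        vol = (np.exp(-((yy - 25.0) ** 2 + (xx - 40.0) ** 2) / (2 * 4.0 ** 2))
               + np.exp(-((yy - 55.0) ** 2 + (xx - 40.0) ** 2) / (2 * 4.0 ** 2)))
        traces = M.trace_filaments(Volume3D(vol.astype(np.float32), 10.0),
                                   [[40.0, 25.0, 40.0], [40.0, 55.0, 40.0]])
        dev0 = np.abs(traces[0].points[:, 1] - 25.0).max()
        dev1 = np.abs(traces[1].points[:, 1] - 55.0).max()
        assert max(dev0, dev1) < 15.0  # never crosses half the spacing

    def test_seed_in_background_flagged_empty(self):
        vol = straight_tube()
        traces = M.trace_filaments(vol, [[5.0, 5.0, 5.0]])
        assert len(traces[0]) == 0


class TestOrientationAndSpacing:
    def _line(self, y, x, n=60, voxel=1.0):
        pts = np.stack([np.arange(n, dtype=float),
                        np.full(n, float(y)), np.full(n, float(x))], axis=1)
        return FilamentTrace(pts, voxel_size_nm=voxel)

    def test_parallel_traces_have_zero_relative_angles(self):
        traces = [self._line(10, 10), self._line(10, 40), self._line(40, 10)]
        table, _ = M.orientation_and_spacing(traces)
        assert np.allclose(table.relative_angle_deg, 0.0, atol=1e-9)

    def test_two_parallel_traces_30nm_apart_give_exact_spacing(self):
        traces = [self._line(10, 10), self._line(10, 40)]  # 30 voxels = 30 nm
        table, summary = M.orientation_and_spacing(traces)
        assert summary["mean_nn_distance_nm"] == pytest.approx(30.0, abs=1e-9)

    def test_meshwork_has_larger_angle_spread_than_parallel(self):
        par = TomogramPhantomSpec(orientation_mode="parallel",
                                  orientation_dispersion=3.0, n_filaments=40)
        mesh = TomogramPhantomSpec(orientation_mode="meshwork",
                                   orientation_dispersion=30.0, n_filaments=40)
        _, t_par = make_tomogram_phantom(par, 180, 1.0, seed=4)
        _, t_mesh = make_tomogram_phantom(mesh, 180, 1.0, seed=4)
        _, s_par = M.orientation_and_spacing(t_par)
        _, s_mesh = M.orientation_and_spacing(t_mesh)
        assert s_mesh["sd_relative_angle_deg"] > s_par["sd_relative_angle_deg"]

    def test_single_trace_spacing_flagged_undefined(self):
        table, summary = M.orientation_and_spacing([self._line(10, 10)])
        assert not summary["spacing_defined"]
        assert np.isnan(table.nn_distance_nm.iloc[0])


class TestFilamentGeometry:
    def test_cylinder_diameter_within_one_voxel(self):
        sigma = 4.84  # FWHM 11.4 voxels = 11.4 nm at 1 nm/voxel
        vol = straight_tube(sigma=sigma)
        trace = FilamentTrace(
            np.stack([np.arange(5.0, 75.0, 2.0),
                      np.full(35, 40.0), np.full(35, 40.0)], axis=1), 1.0)
        diameter, _ = M.filament_geometry(vol, trace)
        assert diameter == pytest.approx(11.4, abs=1.0)

    def test_beaded_tube_period_recovered(self):
        vol = straight_tube(beading_period=20.0)
        trace = FilamentTrace(
            np.stack([np.arange(2.0, 78.0, 2.0),
                      np.full(38, 40.0), np.full(38, 40.0)], axis=1), 1.0)
        _, period = M.filament_geometry(vol, trace)
        assert period == pytest.approx(20.0, abs=1.0)

    def test_unbeaded_cylinder_has_no_period(self):
        vol = straight_tube()
        trace = FilamentTrace(
            np.stack([np.arange(5.0, 75.0, 2.0),
                      np.full(35, 40.0), np.full(35, 40.0)], axis=1), 1.0)
        _, period = M.filament_geometry(vol, trace)
        assert period is None


class TestEllipseFit:
    @staticmethod
    def _ellipse_points(a, b, theta_deg, cx=100.0, cy=80.0, n=40):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        th = np.deg2rad(theta_deg)
        x = cx + a * np.cos(t) * np.cos(th) - b * np.sin(t) * np.sin(th)
        y = cy + a * np.cos(t) * np.sin(th) + b * np.sin(t) * np.cos(th)
        return np.stack([x, y], axis=1)

    def test_circle_radius_50px_at_14nm_gives_1p4_um(self):
        pts = self._ellipse_points(50.0, 50.0, 0.0)
        _, minor_um = M.fit_ellipse_minor_diameter(pts, 14.0)
        assert minor_um == pytest.approx(1.4, rel=1e-6)

    @pytest.mark.parametrize("theta", [0.0, 30.0, 77.0, 120.0])
    def test_minor_axis_invariant_to_orientation(self, theta):
        pts = self._ellipse_points(80.0, 50.0, theta)
        fit, _ = M.fit_ellipse_minor_diameter(pts, 14.0)
        assert fit.minor_semi == pytest.approx(50.0, abs=0.1)
        assert fit.major_semi == pytest.approx(80.0, abs=0.1)

    def test_translation_invariance(self):
        p1 = self._ellipse_points(60.0, 35.0, 40.0, cx=0.0, cy=0.0)
        p2 = p1 + np.array([1234.5, -987.6])
        f1, _ = M.fit_ellipse_minor_diameter(p1, 14.0)
        f2, _ = M.fit_ellipse_minor_diameter(p2, 14.0)
        assert f1.minor_semi == pytest.approx(f2.minor_semi, rel=1e-9)

    def test_one_percent_radial_noise_keeps_error_below_one_percent(self):
        rng = np.random.default_rng(9)
        errors = []
        for _ in range(20):
            pts = self._ellipse_points(55.0, 55.0, 0.0, n=60)
            center = pts.mean(axis=0)
            noisy = center + (pts - center) * (1 + 0.01 * rng.standard_normal((60, 1)))
            _, minor_um = M.fit_ellipse_minor_diameter(noisy, 14.0)
            errors.append(abs(minor_um - 2 * 55 * 14.0 / 1000.0) / (2 * 55 * 14.0 / 1000.0))
        assert np.mean(errors) < 0.01

    def test_collinear_points_rejected(self):
        pts = np.stack([np.arange(10.0), 2.0 * np.arange(10.0)], axis=1)
        with pytest.raises(ValueError, match="collinear"):
            M.fit_ellipse_minor_diameter(pts, 14.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            M.fit_ellipse_minor_diameter(np.zeros((4, 2)), 14.0)


class TestFiberSummary:
    def _fits(self, n_fibers=3, n_slices=1500, diameter=2.0):
        rows = []
        for f in range(n_fibers):
            for s in range(0, n_slices, 50):
                rows.append((s, f, 80.0, 70.0, diameter))
        return pd.DataFrame(rows, columns=["slice", "fiber", "major_semi_px",
                                           "minor_semi_px", "minor_diameter_um"])

    def test_interval_100_on_1500_slices_keeps_at_most_15_per_fiber(self):
        kept, _ = M.fiber_diameter_summary(self._fits(), 100)
        assert kept.groupby("fiber").size().max() <= 15

    def test_single_constant_fiber_gives_mean_d_sd_zero(self):
        kept, summary = M.fiber_diameter_summary(self._fits(n_fibers=1,
                                                            diameter=1.7), 100)
        assert summary["mean_um"] == pytest.approx(1.7)
        assert summary["sd_um"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            M.fiber_diameter_summary(pd.DataFrame(), 100)

    def test_default_generator_mean_recovered_within_5_percent(self):
        from fibrilscope.phantoms import FiberStackSpec, make_fiber_sections
        spec = FiberStackSpec(n_fibers=120)
        contours, truth = make_fiber_sections(spec, seed=3,
                                              slices=range(0, 1500, 300))
        fits = M.fit_contour_table(contours, spec.pixel_size)
        _, summary = M.fiber_diameter_summary(fits, 300)
        assert summary["mean_um"] == pytest.approx(truth.diameter_um.mean(),
                                                   rel=0.05)
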