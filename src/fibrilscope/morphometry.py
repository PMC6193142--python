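"""Filament and fiber morphometry.

Covers tomogram-scale statistics — filament tracing along intensity
ridges, relative orientation and center-to-center spacing, diameter (FWHM
of the radial profile) and axial repeat period — and serial-section fiber
measurement by direct least-squares ellipse fitting, where the minor axis
of an obliquely sectioned circular fiber equals its true diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import FilamentTrace, Volume3D

__all__ = [
    "trace_filaments",
    "orientation_and_spacing",
    "filament_geometry",
    "EllipseFit",
    "fit_ellipse_minor_diameter",
    "fiber_diameter_summary",
]


# --------------------------------------------------------------------------
# tracing


def _local_direction(vol: np.ndarray, point: np.ndarray, radius: int = 4) -> np.ndarray:
    """Ridge direction at a point: eigenvector of the local structure
    tensor with the smallest eigenvalue (intensity varies least along the
    filament axis)."""
    lo = np.maximum(np.round(point).astype(int) - radius, 0)
    hi = np.minimum(np.round(point).astype(int) + radius + 1, vol.shape)
    patch = vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(np.float64)
    if patch.size < 27:
        return np.array([1.0, 0.0, 0.0])
    patch = ndimage.gaussian_filter(patch, 1.0)
    grads = np.gradient(patch)
    tensor = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            tensor[a, b] = (grads[a] * grads[b]).sum()
    vals, vecs = np.linalg.eigh(tensor)
    return vecs[:, 0]  # smallest eigenvalue


def _recenter(vol: np.ndarray, point: np.ndarray, direction: np.ndarray,
              search_radius: float) -> tuple[np.ndarray, float]:
    """Center of intensity in the plane perpendicular to the direction."""
    d = direction / np.linalg.norm(direction)
    a = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    r = int(np.ceil(search_radius))
    u, v = np.meshgrid(np.arange(-r, r + 1, 0.5), np.arange(-r, r + 1, 0.5),
                       indexing="ij")
    keep = u ** 2 + v ** 2 <= search_radius ** 2
    u, v = u[keep], v[keep]
    coords = point[:, None] + e1[:, None] * u[None] + e2[:, None] * v[None]
    vals = ndimage.map_coordinates(vol, coords, order=1, mode="constant", cval=0.0)
    w = np.clip(vals, 0.0, None)
    total = w.sum()
    if total <= 0:
        return point, 0.0
    cu = (w * u).sum() / total
    cv = (w * v).sum() / total
    return point + e1 * cu + e2 * cv, float(vals.mean())


def trace_filaments(volume: Volume3D, seed_points, step: float = 2.0,
                    search_radius: float = 4.0,
                    contrast_floor: float | None = None) -> list[FilamentTrace]:
    """Trace filament centerlines from seed points along intensity ridges.

    From each seed the tracer steps along the local structure-tensor ridge
    direction, re-centering on the perpendicular intensity centroid within
    ``search_radius`` at every step, in both directions until the volume
    edge or until the local contrast falls below ``contrast_floor``
    (default: 25% of the 99th intensity percentile).  Seeds in background
    give an empty (flagged) trace.

    Returns one :class:`FilamentTrace` per seed (possibly with 0 points).
    """
    vol = volume.data.astype(np.float64)
    voxel_nm = volume.voxel_size / 10.0
    if contrast_floor is None:
        contrast_floor = 0.25 * float(np.percentile(vol, 99))
    traces = []
    for seed in np.atleast_2d(np.asarray(seed_points, dtype=float)):
        if np.any(seed < 0) or np.any(seed > np.array(vol.shape) - 1):
            raise ValueError(f"seed {seed} outside the volume")
        center, contrast = _recenter(vol, seed.copy(), np.array([1.0, 0, 0]),
                                     search_radius)
        if contrast < contrast_floor:
            traces.append(_empty_trace(voxel_nm))
            continue
        segments = []
        for sign in (+1.0, -1.0):
            pts = []
            point = center.copy()
            direction = _local_direction(vol, point) * sign
            for _ in range(int(4 * max(vol.shape))):
                d = _local_direction(vol, point)
                if np.dot(d, direction) < 0:
                    d = -d
                direction = d
                nxt = point + step * direction
                if np.any(nxt < 0) or np.any(nxt > np.array(vol.shape) - 1):
                    break
                nxt, contrast = _recenter(vol, nxt, direction, search_radius)
                if contrast < contrast_floor:
                    break
                pts.append(nxt.copy())
                point = nxt
            segments.append(pts)
        pts = segments[1][::-1] + [center] + segments[0]
        if len(pts) < 2:
            traces.append(_empty_trace(voxel_nm))
            continue
        traces.append(FilamentTrace(np.array(pts), voxel_size_nm=voxel_nm))
    return traces


def _empty_trace(voxel_nm: float) -> FilamentTrace:
    t = FilamentTrace.__new__(FilamentTrace)
    t.points = np.empty((0, 3))
    t.voxel_size_nm = voxel_nm
    return t


# --------------------------------------------------------------------------
# orientation and spacing


def bundle_direction(traces) -> np.ndarray:
    """Principal eigenvector of the summed tangent outer products."""
    acc = np.zeros((3, 3))
    for t in traces:
        tg = t.tangents
        acc += tg.T @ tg
    vals, vecs = np.linalg.eigh(acc)
    return vecs[:, -1]


def orientation_and_spacing(traces, n_axial_samples: int = 25):
    """Per-filament relative orientation and nearest-neighbor spacing.

    The bundle direction is the principal eigenvector of the sum of
    tangent outer products over all traces; each filament's relative angle
    is ``arccos(|mean tangent . bundle direction|)`` in [0, 90] degrees.
    Spacing is, per filament, the mean over axial samples of the
    perpendicular center-to-center distance to its nearest neighboring
    trace (the neighbor minimizing that mean; ties broken by lowest trace
    index).

    Returns ``(table, summary)``: a DataFrame with one row per filament
    (``trace``, ``relative_angle_deg``, ``nn_distance_nm``) and a dict
    with means, standard deviations and an orientation r.m.s. dispersion.
    """
    traces = [t for t in traces if len(t) >= 2]
    if len(traces) < 1:
        raise ValueError("need at least one non-empty trace")
    b = bundle_direction(traces)
    voxel_nm = traces[0].voxel_size_nm
    angles = []
    for t in traces:
        c = abs(float(np.dot(t.mean_tangent, b)))
        angles.append(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    angles = np.array(angles)

    spacings = np.full(len(traces), np.nan)
    if len(traces) >= 2:
        for i, ti in enumerate(traces):
            idx = np.linspace(0, len(ti) - 1, min(n_axial_samples, len(ti))).astype(int)
            samples = ti.points[idx]
            # the mean tangent is far less noisy than per-sample tangents;
            # project the axial component out of the closest-approach vector
            tbar = ti.mean_tangent
            best = None
            for j, tj in enumerate(traces):
                if j == i:
                    continue
                diffs = samples[:, None, :] - tj.points[None, :, :]
                d_euc = (diffs ** 2).sum(axis=2)
                nearest = d_euc.argmin(axis=1)
                v = samples - tj.points[nearest]
                perp = v - (v @ tbar)[:, None] * tbar[None]
                d = np.sqrt((perp ** 2).sum(axis=1))
                mean_d = float(d.mean())
                if best is None or mean_d < best[0] - 1e-12:
                    best = (mean_d, j)
            spacings[i] = best[0] * voxel_nm

    table = pd.DataFrame({
        "trace": np.arange(len(traces)),
        "relative_angle_deg": angles,
        "nn_distance_nm": spacings,
    })
    summary = {
        "n_filaments": len(traces),
        "mean_relative_angle_deg": float(angles.mean()),
        "sd_relative_angle_deg": float(angles.std(ddof=1)) if len(angles) > 1 else 0.0,
        "rms_relative_angle_deg": float(np.sqrt((angles ** 2).mean())),
        "mean_nn_distance_nm": float(np.nanmean(spacings)) if len(traces) > 1 else np.nan,
        "sd_nn_distance_nm": float(np.nanstd(spacings, ddof=1)) if len(traces) > 2 else 0.0,
        "spacing_defined": len(traces) > 1,
    }
    return table, summary


# --------------------------------------------------------------------------
# per-filament geometry


def _perpendicular_basis(d: np.ndarray):
    d = d / np.linalg.norm(d)
    a = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(d, e1)


def filament_geometry(volume: Volume3D, trace: FilamentTrace,
                      r_max_vox: float = 12.0, n_angles: int = 16,
                      min_peak_prominence: float = 0.15):
    """Diameter and axial repeat period of one traced filament.

    Diameter is the full width at half maximum of the mean radial
    intensity profile perpendicular to the trace (background at ``r_max``
    subtracted).  Periodicity is the first strong peak of the
    autocorrelation of the intensity profile sampled along the trace;
    traces shorter than one period (or unbeaded filaments) return ``None``
    for the period.

    Returns ``(diameter_nm, period_nm_or_None)``.
    """
    if len(trace) < 2:
        raise ValueError("trace too short")
    vol = volume.data.astype(np.float64)
    voxel_nm = trace.voxel_size_nm
    pts = trace.points
    tangents = trace.tangents

    radii = np.arange(0.0, r_max_vox, 0.5)
    thetas = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    prof_acc = np.zeros(len(radii))
    idx = np.linspace(0, len(pts) - 1, min(40, len(pts))).astype(int)
    for i in idx:
        e1, e2 = _perpendicular_basis(tangents[i])
        dirs = (np.cos(thetas)[:, None] * e1[None] +
                np.sin(thetas)[:, None] * e2[None])  # (n_angles, 3)
        coords = pts[i][None, None, :] + radii[None, :, None] * dirs[:, None, :]
        vals = ndimage.map_coordinates(vol, coords.reshape(-1, 3).T, order=1,
                                       mode="constant", cval=0.0)
        prof_acc += vals.reshape(n_angles, len(radii)).mean(axis=0)
    prof = prof_acc / len(idx)
    base = prof[-3:].mean()
    p = prof - base
    half = p.max() / 2.0
    imax = int(p.argmax())
    below = np.nonzero(p[imax:] < half)[0]
    if len(below) == 0:
        diameter_nm = 2.0 * radii[-1] * voxel_nm
    else:
        j = imax + below[0]
        r1, r2 = radii[j - 1], radii[j]
        v1, v2 = p[j - 1], p[j]
        diameter_nm = 2.0 * (r1 + (v1 - half) / (v1 - v2) * (r2 - r1)) * voxel_nm

    # axial profile resampled at one-voxel arc-length steps
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.r_[0.0, np.cumsum(seg)]
    s = np.arange(0.0, arc[-1], 1.0)
    fine = np.stack([np.interp(s, arc, pts[:, k]) for k in range(3)], axis=1)
    intens = ndimage.map_coordinates(vol, fine.T, order=1, mode="constant", cval=0.0)
    intens = intens - intens.mean()
    period_nm = None
    if len(intens) >= 16:
        ac = np.correlate(intens, intens, mode="full")[len(intens) - 1:]
        ac /= np.maximum(len(intens) - np.arange(len(intens)), 1)
        if ac[0] > 0:
            ac /= ac[0]
            from scipy.signal import find_peaks
            pk, _ = find_peaks(ac[:int(0.8 * len(ac))],
                               prominence=min_peak_prominence * np.ptp(ac))
            pk = pk[pk >= 4]
            if len(pk):
                vmax = ac[pk].max()
                pk = pk[ac[pk] >= 0.5 * vmax]
                lag = int(pk[0])
                if 1 <= lag < len(ac) - 1:
                    den = ac[lag - 1] - 2 * ac[lag] + ac[lag + 1]
                    lagf = lag - 0.5 * (ac[lag + 1] - ac[lag - 1]) / den if den else lag
                else:
                    lagf = lag
                period_nm = float(lagf * voxel_nm)
    return float(diameter_nm), period_nm


# --------------------------------------------------------------------------
# ellipse fitting of fiber contours


@dataclass
class EllipseFit:
    center: tuple[float, float]  # px
    major_semi: float  # px
    minor_semi: float  # px
    orientation: float  # deg
    residual: float  # mean absolute radial misfit, px

    def __post_init__(self) -> None:
        if not self.major_semi >= self.minor_semi > 0:
            raise ValueError("need major >= minor > 0")


def fit_ellipse_minor_diameter(points: np.ndarray,
                               pixel_size: float) -> tuple[EllipseFit, float]:
    """Direct least-squares ellipse fit; minor diameter in micrometers.

    ``points`` is (n, 2) of (x, y) in pixels, n >= 6 and non-collinear;
    ``pixel_size`` is nm/px.  For an oblique plane section of a circular
    cylinder the minor diameter equals the true cylinder diameter.  The
    fit is invariant to rotation and translation of the contour.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 6:
        raise ValueError("need at least 6 (x, y) points")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError("points are collinear")
    from skimage.measure import EllipseModel
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(points)
        if not model:
            raise ValueError("ellipse fit failed (degenerate or hyperbolic conic)")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:  # older scikit-image
        model = EllipseModel()
        if not model.estimate(points):
            raise ValueError("ellipse fit failed (degenerate or hyperbolic conic)")
        xc, yc, a, b, theta = model.params
    if not (np.isfinite([xc, yc, a, b, theta]).all() and a > 0 and b > 0):
        raise ValueError("ellipse fit failed (degenerate or hyperbolic conic)")
    if b > a:
        a, b = b, a
        theta += np.pi / 2.0
    residual = float(np.abs(model.residuals(points)).mean())
    fit = EllipseFit(center=(float(xc), float(yc)), major_semi=float(a),
                     minor_semi=float(b),
                     orientation=float(np.degrees(theta) % 180.0),
                     residual=residual)
    minor_diameter_um = 2.0 * b * pixel_size / 1000.0
    return fit, minor_diameter_um


def fit_contour_table(contours: pd.DataFrame, pixel_size: float) -> pd.DataFrame:
    """Fit every (slice, fiber) contour in a long-format table.

    Returns a DataFrame with slice, fiber, minor/major semi-axes (px) and
    minor diameter (um).
    """
    rows = []
    for (s, f), grp in contours.groupby(["slice", "fiber"], sort=True):
        fit, minor_um = fit_ellipse_minor_diameter(grp[["x", "y"]].to_numpy(),
                                                   pixel_size)
        rows.append((s, f, fit.major_semi, fit.minor_semi, minor_um))
    return pd.DataFrame(rows, columns=["slice", "fiber", "major_semi_px",
                                       "minor_semi_px", "minor_diameter_um"])


def fiber_diameter_summary(fits: pd.DataFrame, sampling_interval: int = 100,
                           bin_width: float = 0.5):
    """Summarize fiber minor diameters, sampling sparsely along the stack.

    Keeps one measurement per fiber per ``sampling_interval`` slices, then
    reports mean, S.D., N and a histogram with ``bin_width`` (um) bins.
    """
    if len(fits) == 0:
        raise ValueError("empty fits table")
    if sampling_interval < 1:
        raise ValueError("sampling_interval must be >= 1")
    fits = fits.copy()
    fits["bin"] = fits["slice"] // sampling_interval
    kept = fits.sort_values(["fiber", "slice"]).groupby(["fiber", "bin"]).head(1)
    d = kept["minor_diameter_um"].to_numpy()
    edges = np.arange(0.0, d.max() + bin_width, bin_width)
    hist, _ = np.histogram(d, bins=edges)
    summary = {
        "n_measurements": int(len(d)),
        "mean_um": float(d.mean()),
        "sd_um": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        "bin_edges_um": edges,
        "histogram": hist,
    }
    return kept.drop(columns="bin"), summary
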