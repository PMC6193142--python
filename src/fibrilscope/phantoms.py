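"""Synthetic phantoms for every input the analysis pipeline consumes.

Four generators, each with ground truth recorded for recovery tests:

* a beaded-microfibril repeat volume (bead / arm / interbead banding,
  exact n-fold symmetry about the filament axis, hollow interbead),
* projection datasets of that volume (random azimuth, in-plane rotation,
  shift, additive Gaussian noise) emulating boxed negative-stain particles,
* tomogram-like volumes of packed beaded filaments with controllable
  orientation dispersion and center-to-center spacing,
* serial-section stacks of elliptical fiber cross sections with a
  controllable (truncated-normal) diameter distribution.

Defaults encode measured microfibril values: 59.2 nm bead-to-bead repeat,
20.8 nm maximum diameter, four interbead arms, eight chains per repeat with
two-fold axial symmetry; 30 nm filament center spacing, 11.4 nm filament
diameter and 60 nm repeat in tomograms; 2.06 +/- 1.40 um fiber diameters in
serial sections.  Density is protein-positive throughout (stain contrast
inversion is not simulated).

All generators are seed-deterministic: identical inputs and seed give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _geometry
from .core import AlignmentRecord, FilamentTrace, ParticleStack, TiltSeries, Volume3D

__all__ = [
    "PhantomSpec",
    "TomogramPhantomSpec",
    "FiberStackSpec",
    "make_microfibril_phantom",
    "make_projection_dataset",
    "make_tomogram_phantom",
    "make_tilt_series",
    "make_fiber_sections",
]


# --------------------------------------------------------------------------
# specs


@dataclass
class PhantomSpec:
    """Geometry of one beaded-filament repeat.

    Lengths are nm.  ``region_boundaries`` gives the fractional z-intervals
    of the repeat occupied by each region; the arm flanks the interbead on
    both sides with different amplitudes, which makes the repeat polar
    (no mirror symmetry along the axis).
    """

    periodicity: float = 59.2  # bead-to-bead repeat, nm
    max_diameter: float = 20.8  # widest (bead) diameter, nm
    interbead_diameter: float = 12.0  # strand-bundle diameter in the interbead, nm
    n_strands: int = 4  # distinct arms/strands in arm+interbead
    n_chains: int = 8  # chains per repeat
    axial_symmetry_order: int = 2  # exact Cn about z
    region_boundaries: dict = field(default_factory=lambda: {
        "bead": (0.0, 0.30),
        "arm": ((0.30, 0.45), (0.85, 1.0)),
        "interbead": (0.45, 0.85),
    })
    density_amplitude: float = 1.0

    def __post_init__(self) -> None:
        for name, val in (("periodicity", self.periodicity),
                          ("max_diameter", self.max_diameter),
                          ("interbead_diameter", self.interbead_diameter)):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if self.axial_symmetry_order < 1:
            raise ValueError("axial_symmetry_order must be >= 1")
        if self.n_chains % self.axial_symmetry_order:
            raise ValueError("n_chains must be a multiple of axial_symmetry_order")


@dataclass
class TomogramPhantomSpec:
    """Packed-filament tomogram phantom parameters (lengths nm, angles deg)."""

    n_filaments: int = 60
    mean_spacing: float = 30.0  # center-to-center nearest-neighbor distance
    filament_diameter: float = 11.4  # FWHM of the tube cross-section
    orientation_mode: str = "parallel"  # "parallel" | "meshwork"
    orientation_dispersion: float = 0.0  # S.D. of tangent tilt, deg
    repeat_period: float = 60.0  # axial beading period, nm

    def __post_init__(self) -> None:
        if self.mean_spacing <= self.filament_diameter:
            raise ValueError("mean_spacing must exceed filament_diameter")
        if self.orientation_dispersion < 0:
            raise ValueError("orientation_dispersion must be >= 0")
        if self.orientation_mode not in ("parallel", "meshwork"):
            raise ValueError("orientation_mode must be 'parallel' or 'meshwork'")


@dataclass
class FiberStackSpec:
    """Serial-section stack of elliptical fiber cross sections.

    The per-fiber true diameter is drawn from a normal truncated at
    0.1 um; the location parameter is adjusted so the post-truncation mean
    equals ``diameter_mean``.  Sections cut the (circular) fibers at
    ``section_obliquity`` degrees, inflating the major axis by
    1/cos(obliquity) while the minor axis stays at the true diameter.
    """

    n_fibers: int = 300
    diameter_mean: float = 2.06  # um
    diameter_sd: float = 1.40  # um
    n_slices: int = 1500
    pixel_size: float = 14.0  # nm / px
    slice_thickness: float = 100.0  # nm
    section_obliquity: float = 30.0  # deg

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.section_obliquity >= 90.0 or self.section_obliquity < 0.0:
            raise ValueError("section_obliquity must be in [0, 90) degrees")


# --------------------------------------------------------------------------
# microfibril repeat phantom


def _cos_sin_multiple(c2: np.ndarray, s2: np.ndarray, m: int):
    """cos/sin of m*(2*theta) by Chebyshev recurrence from cos/sin of 2*theta.

    Built from even powers of the unit direction vector only, so the result
    is bitwise invariant under the exact 180-degree grid rotation.
    """
    ck, sk = np.ones_like(c2), np.zeros_like(c2)  # m = 0
    for _ in range(m):
        ck, sk = ck * c2 - sk * s2, sk * c2 + ck * s2
    return ck, sk


def _angular_bumps(c2: np.ndarray, s2: np.ndarray, k: int, power: int = 3) -> np.ndarray:
    """k localized angular bumps, exact for even k (from cos(k*theta))."""
    if k % 2:
        raise ValueError("angular bump order must be even")
    ck, _ = _cos_sin_multiple(c2, s2, k // 2)
    return ((1.0 + ck) / 2.0) ** power


def _raised_cosine_window(frac: np.ndarray, lo: float, hi: float,
                          soft: float = 0.04) -> np.ndarray:
    """Smooth periodic window on the fractional repeat coordinate."""
    d = (frac - lo) % 1.0
    width = (hi - lo) % 1.0 or 1.0
    w = np.zeros_like(frac)
    inside = d < width
    t = np.minimum(d, width - d)  # distance to the nearest interval edge
    w[inside] = np.where(t[inside] >= soft, 1.0,
                         0.5 - 0.5 * np.cos(np.pi * t[inside] / soft))
    return w


def _effective_order(natural: int, symmetry_order: int) -> int:
    """Smallest multiple of the imposed Cn order that is >= natural and even."""
    k = int(np.lcm(natural, symmetry_order))
    return k if k % 2 == 0 else 2 * k


def make_microfibril_phantom(spec: PhantomSpec, box_px: int = 128,
                             voxel_size: float = 8.0) -> Volume3D:
    """Build a beaded-repeat phantom volume on a cubic grid.

    Parameters
    ----------
    spec : PhantomSpec
    box_px : cubic box edge, voxels
    voxel_size : Angstrom per voxel

    The volume is periodic along z with period ``periodicity``; it carries
    exact Cn symmetry about z for ``n = spec.axial_symmetry_order`` (the
    180-degree rotation is bitwise exact for even n).  The bead is a soft
    solid disk whose azimuthally averaged profile crosses half maximum at
    ``max_diameter / 2``; the interbead is a hollow bundle of
    ``n_strands`` strands.
    """
    if box_px * voxel_size < spec.periodicity * 10.0:
        raise ValueError(
            f"box of {box_px} px at {voxel_size} A/voxel spans "
            f"{box_px * voxel_size:.0f} A < one repeat ({spec.periodicity * 10:.0f} A)"
        )
    n = box_px
    period_vox = spec.periodicity * 10.0 / voxel_size
    c = (n - 1) / 2.0
    z = np.arange(n, dtype=np.float64)
    yy, xx = np.meshgrid(np.arange(n, dtype=np.float64) - c,
                         np.arange(n, dtype=np.float64) - c, indexing="ij")
    r2 = yy * yy + xx * xx
    r = np.sqrt(r2)
    with np.errstate(invalid="ignore", divide="ignore"):
        c2 = np.where(r2 > 0, (xx * xx - yy * yy) / r2, 1.0)
        s2 = np.where(r2 > 0, 2.0 * xx * yy / r2, 0.0)

    sym = spec.axial_symmetry_order
    k_bead = _effective_order(2, sym)
    k_strand = _effective_order(spec.n_strands, sym)

    r_bead = spec.max_diameter * 10.0 / 2.0 / voxel_size  # vox
    r_ib = spec.interbead_diameter * 10.0 / 2.0 / voxel_size
    r_arm_in, r_arm_out = 0.55 * r_bead, 0.85 * r_bead
    edge = 1.0  # vox, disk edge softness
    sig_r = 1.4  # vox, strand radial width

    # radial factors (2D, azimuth-exact)
    bead_disk = 1.0 / (1.0 + np.exp((r - r_bead) / edge))
    ck_b, _ = _cos_sin_multiple(c2, s2, k_bead // 2)
    bead_2d = bead_disk * (1.0 + 0.25 * ck_b * np.clip(r / r_bead, 0.0, 1.0))

    strand_b = _angular_bumps(c2, s2, k_strand)
    arm_2d_a = np.exp(-((r - r_arm_out) ** 2) / (2 * sig_r ** 2)) * strand_b
    arm_2d_b = np.exp(-((r - r_arm_in) ** 2) / (2 * sig_r ** 2)) * strand_b
    ib_2d = np.exp(-((r - r_ib) ** 2) / (2 * sig_r ** 2)) * (0.35 + 0.65 * strand_b)

    # axial envelopes on the fractional repeat coordinate; the banding is
    # strongly asymmetric along the axis (polar repeat): the bead density
    # ramps toward one end, the two arm bands differ in amplitude and the
    # interbead tapers, so projections distinguish the two filament ends
    frac = (z / period_vox) % 1.0
    bounds = spec.region_boundaries
    env_bead = _raised_cosine_window(frac, *bounds["bead"])
    b_lo, b_hi = bounds["bead"]
    t_bead = ((frac - b_lo) % 1.0) / ((b_hi - b_lo) % 1.0 or 1.0)
    env_bead = env_bead * (0.5 + 1.0 * np.clip(t_bead, 0.0, 1.0))
    (a1_lo, a1_hi), (a2_lo, a2_hi) = bounds["arm"]
    env_arm_a = _raised_cosine_window(frac, a1_lo, a1_hi)
    env_arm_b = _raised_cosine_window(frac, a2_lo, a2_hi)
    ib_lo, ib_hi = bounds["interbead"]
    env_ib = _raised_cosine_window(frac, ib_lo, ib_hi)
    t_ib = ((frac - ib_lo) % 1.0) / ((ib_hi - ib_lo) % 1.0 or 1.0)
    env_ib = env_ib * (1.2 - 0.6 * np.clip(t_ib, 0.0, 1.0))

    amp = spec.density_amplitude
    vol = (
        amp * env_bead[:, None, None] * bead_2d[None]
        + 0.9 * amp * env_arm_a[:, None, None] * arm_2d_a[None]
        + 0.4 * amp * env_arm_b[:, None, None] * arm_2d_b[None]
        + 0.7 * amp * env_ib[:, None, None] * ib_2d[None]
    )
    return Volume3D(vol.astype(np.float32), voxel_size)


# --------------------------------------------------------------------------
# projection dataset


def _project_z(volume: Volume3D, azimuth: float) -> np.ndarray:
    # matches reconstruct.project_about_axis (Radon-transform convention)
    rot = _geometry.rotate_volume_z(volume.data.astype(np.float64),
                                    (-azimuth) % 360.0)
    return rot.sum(axis=1)


def make_projection_dataset(volume: Volume3D, n: int, snr: float = 0.3,
                            shift_max: float = 8.0, seed: int = 0,
                            psi_max: float = 360.0):
    """Simulate a boxed-particle dataset from a phantom volume.

    Each image is the projection of ``volume`` rotated about z by a uniform
    random azimuth, rotated in-plane by a uniform random psi in
    ``[0, psi_max)``, shifted by uniform shifts up to ``shift_max`` px, with
    additive zero-mean Gaussian noise of variance (signal variance / snr).
    Pass ``snr=np.inf`` to disable noise.

    Returns ``(ParticleStack, list[AlignmentRecord])`` with the ground-truth
    transforms.  Identical inputs and seed give a bit-identical stack.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not snr > 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    images = np.empty((n, volume.shape[0], volume.shape[2]), dtype=np.float32)
    records: list[AlignmentRecord] = []
    # draw all randomness up front so the stream is independent of layout
    phis = rng.uniform(0.0, 360.0, size=n)
    psis = rng.uniform(0.0, psi_max, size=n)
    shifts = rng.uniform(-shift_max, shift_max, size=(n, 2)) if shift_max > 0 \
        else np.zeros((n, 2))
    proj_cache: dict[float, np.ndarray] = {}
    for i in range(n):
        phi = float(phis[i])
        if phi not in proj_cache:
            proj_cache[phi] = _project_z(volume, phi)
        img = proj_cache[phi]
        if psis[i] != 0.0:
            img = _geometry.rotate_image(img, psis[i])
        dy, dx = shifts[i]
        if dy != 0.0 or dx != 0.0:
            img = _geometry.shift_image(img, dy, dx)
        sig_var = float(img.var())
        if np.isfinite(snr):
            img = img + rng.normal(0.0, np.sqrt(sig_var / snr), size=img.shape)
        images[i] = img
        records.append(AlignmentRecord(psi=psis[i], dx=float(dx), dy=float(dy),
                                       phi=phi, ref_index=0, score=1.0))
    stack = ParticleStack(images, volume.voxel_size,
                          provenance=f"synthetic projections seed={seed} snr={snr}")
    return stack, records


# --------------------------------------------------------------------------
# tomogram phantom


def _hex_centers(box_yx: tuple[int, int], spacing: float) -> np.ndarray:
    """Hexagonal lattice of (y, x) centers filling the field with margin."""
    a = spacing
    dy = a * np.sqrt(3.0) / 2.0
    margin = a / 4.0
    centers = []
    row = 0
    y = margin
    while y < box_yx[0] - margin:
        x0 = margin + (a / 2.0 if row % 2 else 0.0)
        x = x0
        while x < box_yx[1] - margin:
            centers.append((y, x))
            x += a
        y += dy
        row += 1
    return np.array(centers, dtype=float)


def make_tomogram_phantom(spec: TomogramPhantomSpec, box: int | tuple = 200,
                          voxel_size: float = 1.0, seed: int = 0):
    """Build a packed-filament tomogram-like volume plus truth traces.

    Parameters
    ----------
    box : cubic edge (or (nz, ny, nx)) in voxels
    voxel_size : nm per voxel (the returned Volume3D stores Angstrom)

    Filament centers sit on a jittered hexagonal packing with
    nearest-neighbor distance about ``mean_spacing``; tangents follow the
    orientation mode (all parallel to z, or tilted by a folded-normal polar
    angle of S.D. ``orientation_dispersion`` with uniform azimuth).  Tubes
    have a Gaussian cross-section of FWHM ``filament_diameter`` and a
    raised-cosine axial beading of period ``repeat_period``.

    Returns ``(Volume3D, list[FilamentTrace])``.
    """
    shape = (box, box, box) if np.isscalar(box) else tuple(box)
    nz, ny, nx = shape
    spacing_vox = spec.mean_spacing / voxel_size
    if min(ny, nx) < 2.0 * spacing_vox:
        raise ValueError("box too small to pack two filaments at mean_spacing")
    rng = np.random.default_rng(seed)
    centers = _hex_centers((ny, nx), spacing_vox)
    if len(centers) < 2:
        raise ValueError("packing infeasible: fewer than 2 filaments fit")
    order = rng.permutation(len(centers))[: spec.n_filaments]
    centers = centers[np.sort(order)]
    centers = centers + rng.normal(0.0, 0.02 * spacing_vox, size=centers.shape)

    n_fil = len(centers)
    if spec.orientation_mode == "parallel" and spec.orientation_dispersion == 0:
        tilts = np.zeros(n_fil)
    else:
        tilts = np.abs(rng.normal(0.0, spec.orientation_dispersion, size=n_fil))
    azims = rng.uniform(0.0, 2 * np.pi, size=n_fil)
    phases = rng.uniform(0.0, 2 * np.pi, size=n_fil)

    sigma_t = spec.filament_diameter / voxel_size / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    win = int(np.ceil(4.0 * sigma_t))
    period_vox = spec.repeat_period / voxel_size

    vol = np.zeros(shape, dtype=np.float32)
    traces: list[FilamentTrace] = []
    zs = np.arange(nz, dtype=float)
    for i in range(n_fil):
        slope = np.tan(np.deg2rad(tilts[i]))
        dy_dz = slope * np.sin(azims[i])
        dx_dz = slope * np.cos(azims[i])
        cy = centers[i, 0] + (zs - nz / 2.0) * dy_dz
        cx = centers[i, 1] + (zs - nz / 2.0) * dx_dz
        beading = 1.0 + 0.5 * np.cos(2 * np.pi * zs / period_vox + phases[i])
        inside = (cy > -win) & (cy < ny + win) & (cx > -win) & (cx < nx + win)
        for zi in np.nonzero(inside)[0]:
            y0 = int(np.floor(cy[zi])) - win
            x0 = int(np.floor(cx[zi])) - win
            y1, x1 = y0 + 2 * win + 1, x0 + 2 * win + 1
            ys = np.arange(max(y0, 0), min(y1, ny))
            xs = np.arange(max(x0, 0), min(x1, nx))
            if len(ys) == 0 or len(xs) == 0:
                continue
            gy = np.exp(-((ys - cy[zi]) ** 2) / (2 * sigma_t ** 2))
            gx = np.exp(-((xs - cx[zi]) ** 2) / (2 * sigma_t ** 2))
            vol[zi, ys[0]: ys[-1] + 1, xs[0]: xs[-1] + 1] += (
                beading[zi] * np.outer(gy, gx)
            ).astype(np.float32)
        pts_mask = (cy >= 0) & (cy <= ny - 1) & (cx >= 0) & (cx <= nx - 1)
        zi = np.nonzero(pts_mask)[0]
        if len(zi) >= 2:
            pts = np.stack([zs[zi], cy[zi], cx[zi]], axis=1)
            traces.append(FilamentTrace(pts, voxel_size_nm=voxel_size))
    return Volume3D(vol, voxel_size * 10.0), traces


# --------------------------------------------------------------------------
# tilt series


def make_tilt_series(volume: Volume3D, angle_min: float = -65.0,
                     angle_max: float = 65.0, step: float = 1.0) -> TiltSeries:
    """Project a volume over a single-axis tilt range about the y axis.

    One projection per angle from ``angle_min`` to ``angle_max`` inclusive in
    ``step``-degree increments (the -65..+65 default at 1-degree steps gives
    131 images).  Images are (y, x); the beam runs along z at zero tilt.
    """
    if not angle_min < angle_max:
        raise ValueError("empty tilt range: angle_min must be < angle_max")
    if step <= 0:
        raise ValueError("step must be positive")
    angles = np.arange(angle_min, angle_max + step / 2.0, step)
    data = volume.data.astype(np.float64)
    images = np.empty((len(angles), volume.shape[1], volume.shape[2]),
                      dtype=np.float32)
    for i, a in enumerate(angles):
        # Radon-transform angle convention, matching reconstruct.wbp_tilt
        images[i] = _geometry.rotate_volume_y(data, -a).sum(axis=0)
    return TiltSeries(images, angles, volume.voxel_size)


# --------------------------------------------------------------------------
# fiber sections


def _truncnorm_params_for_moments(target_mean: float, target_sd: float,
                                  lower: float) -> tuple[float, float]:
    """(loc, scale) whose ``lower``-truncated normal has the target moments."""
    def resid(p):
        loc, scale = p
        scale = abs(scale)
        a = (lower - loc) / scale
        return (stats.truncnorm.mean(a, np.inf, loc=loc, scale=scale) - target_mean,
                stats.truncnorm.std(a, np.inf, loc=loc, scale=scale) - target_sd)

    sol = optimize.fsolve(resid, x0=(target_mean, target_sd), full_output=True)
    (loc, scale), _, ok, _ = sol
    if ok != 1:
        # fall back to matching the mean only
        loc = float(optimize.brentq(
            lambda m: stats.truncnorm.mean((lower - m) / target_sd, np.inf,
                                           loc=m, scale=target_sd) - target_mean,
            target_mean - 4 * target_sd, target_mean + target_sd))
        return loc, target_sd
    return float(loc), float(abs(scale))


def make_fiber_sections(spec: FiberStackSpec, seed: int = 0,
                        slices=None, points_per_contour: int = 32,
                        contour_noise: float = 0.005):
    """Generate elliptical fiber cross-section contours plus a truth table.

    Each fiber is a circular cylinder of constant true diameter running
    through the whole stack; sections cut it at ``section_obliquity``, so
    its contour is an ellipse with minor axis equal to the true diameter
    and major axis inflated by 1/cos(obliquity).  Fiber centers drift
    slightly between slices.  ``contour_noise`` is fractional radial jitter
    on the contour points.

    Parameters
    ----------
    slices : iterable of slice indices to generate (default: every slice —
        note this is large for the 1500-slice default; pass e.g.
        ``range(0, 1500, 100)`` to emulate sparse sampling).

    Returns
    -------
    contours : DataFrame with columns (slice, fiber, x, y) in pixels
    truth : DataFrame with columns (fiber, diameter_um)
    """
    rng = np.random.default_rng(seed)
    lower = 0.1  # um, truncation floor
    loc, scale = _truncnorm_params_for_moments(spec.diameter_mean,
                                               spec.diameter_sd, lower)
    a = (lower - loc) / scale
    diameters = stats.truncnorm.rvs(a, np.inf, loc=loc, scale=scale,
                                    size=spec.n_fibers, random_state=rng)

    px_per_um = 1000.0 / spec.pixel_size
    field = 4096.0  # px
    centers = rng.uniform(0.2 * field, 0.8 * field, size=(spec.n_fibers, 2))
    orients = rng.uniform(0.0, np.pi, size=spec.n_fibers)
    drift = rng.normal(0.0, 2.0, size=(spec.n_fibers, spec.n_slices, 2)).cumsum(axis=1)

    if slices is None:
        slices = range(spec.n_slices)
    slices = [int(s) for s in slices]
    if any(s < 0 or s >= spec.n_slices for s in slices):
        raise ValueError("slice index out of range")

    inflate = 1.0 / np.cos(np.deg2rad(spec.section_obliquity))
    t = np.linspace(0.0, 2 * np.pi, points_per_contour, endpoint=False)
    rows = []
    for f in range(spec.n_fibers):
        b = diameters[f] / 2.0 * px_per_um  # minor semi-axis, px
        amaj = b * inflate
        ct, st = np.cos(orients[f]), np.sin(orients[f])
        ex, ey = amaj * np.cos(t), b * np.sin(t)
        for s in slices:
            cx = centers[f, 0] + drift[f, s, 0]
            cy = centers[f, 1] + drift[f, s, 1]
            jitter = 1.0 + contour_noise * rng.standard_normal(points_per_contour)
            px = cx + (ex * ct - ey * st) * jitter
            py = cy + (ex * st + ey * ct) * jitter
            for xp, yp in zip(px, py):
                rows.append((s, f, xp, yp))
    contours = pd.DataFrame(rows, columns=["slice", "fiber", "x", "y"])
    truth = pd.DataFrame({"fiber": np.arange(spec.n_fibers),
                          "diameter_um": diameters})
    return contours, truth
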