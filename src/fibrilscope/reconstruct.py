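"""3D model building and iterative projection-matching refinement.

The reconstruction operator is weighted back-projection (ramp filter in
the projection-transform direction, linear back-projection) applied
slice-by-slice perpendicular to the rotation axis — the filament geometry
back-projects about the filament (z) axis, the tomographic geometry about
the single tilt (y) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import iradon

from . import _geometry
from .core import (AlignmentRecord, ParticleStack, TiltSeries, Volume3D,
                   records_to_frame)
from .match import _rotate_shift, invert_record

__all__ = [
    "RefinementConfig",
    "RefinementResult",
    "cylindrical_initial_model",
    "project_about_axis",
    "wbp_filament",
    "wbp_tilt",
    "impose_cn",
    "lowpass_volume",
    "refine_projection_matching",
    "reconstruct_halves",
    "iso_level_for_volume_fraction",
    "mass_to_volume",
    "volume_to_mass",
    "axial_periodicity",
    "max_diameter_fwhm",
]

# protein density 1.35 g/cm^3 expressed in Da per cubic Angstrom
PROTEIN_DENSITY_DA_PER_A3 = 1.35 * 6.02214076e23 / 1e24


@dataclass
class RefinementConfig:
    """Projection-matching refinement parameters.

    ``azimuth_step`` sets the reference grid about the filament axis;
    with ``symmetry_order`` n the grid only needs to cover 360/n degrees.
    The in-plane search is a local window of ``psi_local_range`` degrees
    around each particle's current psi (particles arrive pre-aligned
    in plane from the reference-free stage).
    """

    azimuth_step: float = 5.0
    n_iterations: int = 5
    symmetry_order: int = 2
    lowpass_each_iter: float = 20.0  # Angstrom
    halfset_mode: bool = False
    halfset_seed: int = 17
    shift_max: int = 8
    psi_local_range: float = 10.0
    psi_local_step: float = 5.0
    min_changed_fraction: float = 0.02  # stop when fewer assignments change

    def __post_init__(self) -> None:
        if 360.0 % self.azimuth_step:
            raise ValueError("azimuth_step must divide 360")
        if self.symmetry_order < 1:
            raise ValueError("symmetry_order must be >= 1")


@dataclass
class RefinementResult:
    volume: Volume3D
    records: list
    log: pd.DataFrame
    halves: tuple[Volume3D, Volume3D] | None = None
    stopped_reason: str = "completed"


# --------------------------------------------------------------------------
# projection and back-projection


def project_about_axis(volume: Volume3D, azimuth: float) -> np.ndarray:
    """Project the volume along y after rotating about z by ``azimuth``.

    Returns a (z, x) image with the filament axis vertical.  Linear in the
    volume; azimuth is reduced mod 360.
    """
    # rotating the volume by -azimuth and summing matches the Radon
    # transform convention that wbp_filament's back-projection inverts
    rot = _geometry.rotate_volume_z(volume.data.astype(np.float64),
                                    (-azimuth) % 360.0)
    return rot.sum(axis=1)


def _wbp_from_sinograms(sinos: np.ndarray, thetas: np.ndarray,
                        output_size: int) -> np.ndarray:
    """Apply ramp-filtered back-projection per slice.

    ``sinos`` is (n_slices, detector, n_angles); returns
    (n_slices, output_size, output_size).
    """
    out = np.empty((sinos.shape[0], output_size, output_size), dtype=np.float32)
    for i in range(sinos.shape[0]):
        out[i] = iradon(sinos[i], theta=thetas, filter_name="ramp",
                        interpolation="linear", circle=True,
                        output_size=output_size, preserve_range=True)
    return out


def wbp_filament(stack: ParticleStack, records, voxel_size: float) -> Volume3D:
    """Weighted back-projection of in-plane-aligned particles about z.

    Each particle is brought to the reference frame (inverse shift and
    in-plane rotation from its record) and back-projected at its assigned
    azimuth.  Particles sharing an azimuth are averaged first, so each
    distinct viewing direction enters with equal weight.
    """
    if len(records) != len(stack):
        raise ValueError("records must align 1:1 with the stack")
    if len(stack) == 0:
        raise ValueError("empty stack")
    phis = np.array([r.phi for r in records])
    uniq = np.unique(np.round(phis, 6))
    if len(uniq) < 3:
        import warnings
        warnings.warn("fewer than 3 distinct azimuths: reconstruction will be "
                      "severely anisotropic", RuntimeWarning, stacklevel=2)
    h, w = stack.box
    sino = np.zeros((h, w, len(uniq)))
    counts = np.zeros(len(uniq))
    index = {a: i for i, a in enumerate(uniq)}
    for img, rec in zip(stack.data, records):
        j = index[np.round(rec.phi, 6)]
        sino[:, :, j] += invert_record(img.astype(np.float64), rec)
        counts[j] += 1
    sino /= counts[None, None, :]
    vol = _wbp_from_sinograms(sino, uniq, output_size=w)
    return Volume3D(vol, voxel_size)


def wbp_tilt(series: TiltSeries, voxel_size: float | None = None) -> Volume3D:
    """Weighted back-projection of a single-axis tilt series.

    The tilt axis is y; each (z, x) plane is reconstructed independently
    from its sinogram over the recorded angles.  With a limited tilt range
    the unsampled missing wedge makes resolution anisotropic — features
    blur along the beam (z) direction.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 tilt images")
    data = series.data.astype(np.float64)
    n_tilt, ny, nx = data.shape
    voxel = voxel_size if voxel_size is not None else series.pixel_size
    # per y-slice sinogram: (detector x, angles)
    sinos = np.transpose(data, (1, 2, 0))  # (y, x, tilt)
    vol_yzx = _wbp_from_sinograms(sinos, series.angles, output_size=nx)
    # slices come back as (z, x) per y; reorder to (z, y, x)
    return Volume3D(np.transpose(vol_yzx, (1, 0, 2)), voxel)


# --------------------------------------------------------------------------
# symmetry, filtering, initial model


def impose_cn(volume: Volume3D, n: int) -> Volume3D:
    """Average the n azimuthal rotations by 360k/n about z.

    Idempotent and norm-non-increasing; exact (flip-based) for right-angle
    rotations, so C2 and C4 imposition are machine-precision operations.
    """
    if n < 1:
        raise ValueError("symmetry order must be >= 1")
    if n == 1:
        return volume.copy()
    data = volume.data.astype(np.float64)
    acc = np.zeros_like(data)
    for k in range(n):
        acc += _geometry.rotate_volume_z(data, 360.0 * k / n)
    return Volume3D(acc / n, volume.voxel_size)


def lowpass_volume(volume: Volume3D, resolution: float) -> Volume3D:
    """Hard spherical low-pass to ``resolution`` Angstrom."""
    data = volume.data.astype(np.float64)
    freqs = [np.fft.fftfreq(s, d=volume.voxel_size) for s in data.shape]
    kz, ky, kx = np.meshgrid(*freqs, indexing="ij")
    keep = (kz * kz + ky * ky + kx * kx) <= (1.0 / resolution) ** 2
    out = np.fft.ifftn(np.fft.fftn(data) * keep).real
    return Volume3D(out, volume.voxel_size)


def cylindrical_initial_model(average_image: np.ndarray, voxel_size: float,
                              lowpass: float | None = 20.0) -> Volume3D:
    """Cylindrically symmetric starting model from a 2D class average.

    Every azimuthal view of a rotationally symmetric body is identical, so
    the model is recovered by ramp-filtered back-projection of the average
    replicated over a dense azimuth grid, then azimuthally averaged to make
    the symmetry exact.  The result reprojects to (a smoothed copy of) the
    input at any azimuth and is low-pass filtered to ``lowpass`` Angstrom.
    """
    average_image = np.asarray(average_image, dtype=np.float64)
    if average_image.ndim != 2 or average_image.shape[0] != average_image.shape[1]:
        raise ValueError("average image must be square")
    n = average_image.shape[0]
    if not average_image.any():
        return Volume3D(np.zeros((n, n, n), dtype=np.float32), voxel_size)
    thetas = np.arange(0.0, 360.0, 5.0)
    sinos = np.repeat(average_image[:, :, None], len(thetas), axis=2)
    vol = _wbp_from_sinograms(sinos, thetas, output_size=n).astype(np.float64)
    # enforce exact rotational symmetry: azimuthal average by radial binning
    c = (n - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
    r = np.hypot(yy, xx)
    r_idx = np.clip(np.round(r).astype(int), 0, n - 1)
    cnts = np.bincount(r_idx.ravel(), minlength=n)
    filled = cnts > 0
    r_centers = np.bincount(r_idx.ravel(), weights=r.ravel(), minlength=n)[filled] / cnts[filled]
    out = np.empty_like(vol)
    for z in range(n):
        prof = np.bincount(r_idx.ravel(), weights=vol[z].ravel(), minlength=n)
        out[z] = np.interp(r, r_centers, prof[filled] / cnts[filled])
    model = Volume3D(out, voxel_size)
    if lowpass is not None:
        nyquist_res = 2.0 * voxel_size
        if lowpass > nyquist_res:
            model = lowpass_volume(model, lowpass)
    return model


def image_axis_angle(image: np.ndarray) -> float:
    """Angle (deg) of the intensity principal axis from the vertical.

    Computed from the second moments of the positive part of the image;
    returned in (-90, 90].  Used to straighten a filament class average so
    the filament axis is vertical before building the cylindrical model.
    """
    w = np.clip(np.asarray(image, dtype=np.float64), 0.0, None) ** 2
    total = w.sum()
    if total == 0:
        return 0.0
    ys, xs = np.mgrid[: image.shape[0], : image.shape[1]]
    ym = (w * ys).sum() / total
    xm = (w * xs).sum() / total
    dy, dx = ys - ym, xs - xm
    syy = (w * dy * dy).sum() / total
    sxx = (w * dx * dx).sum() / total
    sxy = (w * dy * dx).sum() / total
    vals, vecs = np.linalg.eigh(np.array([[syy, sxy], [sxy, sxx]]))
    vy, vx = vecs[:, np.argmax(vals)]
    ang = np.degrees(np.arctan2(vx, vy))
    if ang > 90.0:
        ang -= 180.0
    elif ang <= -90.0:
        ang += 180.0
    return float(ang)


def verticalize_records(stack: ParticleStack, records) -> tuple[list, np.ndarray, float]:
    """Rotate an aligned particle set so the filament axis is vertical.

    Adds a global in-plane offset to every record's psi so that the
    aligned average's principal axis aligns with the image rows, and
    returns ``(records, new_average, applied_offset_deg)``.
    """
    from .match import average_aligned
    avg = average_aligned(stack, records)
    # adding delta to every psi rotates the average by -delta
    ang = image_axis_angle(avg)
    best = None
    for delta in (ang, -ang):
        cand = [AlignmentRecord(psi=r.psi + delta, dx=r.dx, dy=r.dy, phi=r.phi,
                                ref_index=r.ref_index, score=r.score)
                for r in records]
        cand_avg = average_aligned(stack, cand)
        residual = abs(image_axis_angle(cand_avg))
        if best is None or residual < best[0]:
            best = (residual, cand, cand_avg, delta)
    return best[1], best[2], best[3]


# --------------------------------------------------------------------------
# refinement loop


def _fast_align_to_references(data: np.ndarray, refs: np.ndarray,
                              psis_current: np.ndarray, cfg: RefinementConfig,
                              ref_phis: np.ndarray,
                              mask: np.ndarray | None = None):
    """Local-window alignment of every particle to every reference.

    Scoring is normalized cross-correlation by circular FFT restricted to
    shifts within ``cfg.shift_max``; with a mask, the masked-NCC local
    normalization is used (mask fixed in the reference frame).
    """
    n, h, w = data.shape
    s = int(cfg.shift_max)
    wy = np.r_[np.arange(0, s + 1), np.arange(h - s, h)]
    wx = np.r_[np.arange(0, s + 1), np.arange(w - s, w)]
    win = np.ix_(wy, wx)
    offs_y = np.where(wy <= s, wy, wy - h).astype(float)
    offs_x = np.where(wx <= s, wx, wx - w).astype(float)

    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    mask = np.asarray(mask).astype(bool)
    m = mask.astype(np.float64)
    n_true = m.sum()
    fm = np.conj(np.fft.rfft2(m))
    ft_list, t_energy = [], []
    for ref in refs:
        t0 = (ref - ref[mask].mean()) * m
        ft_list.append(np.conj(np.fft.rfft2(t0)))
        t_energy.append((t0 * t0).sum())

    d_psi = np.arange(-cfg.psi_local_range, cfg.psi_local_range + 1e-9,
                      cfg.psi_local_step)
    # reference-free pre-alignment leaves per-particle polarity ambiguous
    # (the repeat is polar but the evolving 2D template is a polarity
    # mixture), so the 3D stage also searches the 180-degree-flipped
    # in-plane orientation and lets the model polarize over iterations
    d_psi = np.concatenate([d_psi, d_psi + 180.0])
    n_refs = len(ft_list)
    scores = np.full((n, n_refs), -np.inf)
    params = np.zeros((n, n_refs, 3))  # psi, dy, dx at each ref's best
    for i in range(n):
        for dp in d_psi:
            psi = (psis_current[i] + dp) % 360.0
            rot = _geometry.rotate_image(data[i], -psi)
            fi = np.fft.rfft2(rot)
            s1 = np.fft.irfft2(fi * fm, s=(h, w))[win]
            s2 = np.fft.irfft2(np.fft.rfft2(rot * rot) * fm, s=(h, w))[win]
            var_p = np.clip(s2 - s1 * s1 / n_true, 1e-12, None)
            for ri, ft in enumerate(ft_list):
                cc = np.fft.irfft2(fi * ft, s=(h, w))[win]
                cc = cc / np.sqrt(t_energy[ri] * var_p)
                iy, ix = np.unravel_index(int(cc.argmax()), cc.shape)
                score = float(cc[iy, ix])
                if score > scores[i, ri]:
                    dy, dx = _rotate_shift(offs_y[iy], offs_x[ix], psi)
                    scores[i, ri] = score
                    params[i, ri] = (psi, dy, dx)
    # the component of the model common to every azimuth (e.g. the
    # cylindrical average) attracts all particles to whichever reference
    # happens to carry most of it; centering the score matrix per
    # reference makes the assignment sensitive to the particle-specific
    # (azimuthal) differences instead
    centered = scores - scores.mean(axis=0, keepdims=True)
    records = []
    for i in range(n):
        ri = int(np.argmax(centered[i]))
        psi, dy, dx = params[i, ri]
        records.append(AlignmentRecord(psi=psi, dx=dx, dy=dy,
                                       phi=float(ref_phis[ri]), ref_index=ri,
                                       score=min(float(scores[i, ri]), 1.0)))
    return records


def _reconstruct_from(stack: ParticleStack, records, cfg: RefinementConfig,
                      indices=None) -> Volume3D:
    if indices is not None:
        sub = ParticleStack(stack.data[indices], stack.pixel_size)
        recs = [records[i] for i in indices]
    else:
        sub, recs = stack, records
    vol = wbp_filament(sub, recs, sub.pixel_size)
    vol = impose_cn(vol, cfg.symmetry_order)
    if cfg.lowpass_each_iter and cfg.lowpass_each_iter > 2 * sub.pixel_size:
        vol = lowpass_volume(vol, cfg.lowpass_each_iter)
    return vol


def refine_projection_matching(stack: ParticleStack, init: Volume3D,
                               cfg: RefinementConfig,
                               records=None,
                               score_mask: np.ndarray | None = None) -> RefinementResult:
    """Iterative projection-matching refinement.

    Per iteration: project the model at ``azimuth_step`` increments over
    the symmetry-reduced azimuth range, align every particle to every
    reference (local in-plane window, shifts up to ``shift_max``),
    reconstruct by weighted back-projection, impose the symmetry, low-pass
    filter, and log the mean score and the fraction of changed azimuth
    assignments.  Stops at ``n_iterations``, when fewer than
    ``min_changed_fraction`` of assignments change, or when the mean score
    drops on two consecutive iterations (divergence guard).
    """
    if stack.box[0] != init.shape[0] or stack.box[1] != init.shape[2]:
        raise ValueError("initial model size does not match the stack box")
    data = stack.data.astype(np.float64)
    n = len(stack)
    if records is None:
        records = [AlignmentRecord() for _ in range(n)]
    psis = np.array([r.psi for r in records])
    assigned = np.full(n, -1)
    model = init
    log_rows = []
    prev_scores = []
    reason = "completed"
    for it in range(cfg.n_iterations):
        ref_phis = np.arange(0.0, 360.0 / cfg.symmetry_order, cfg.azimuth_step)
        refs = np.stack([project_about_axis(model, p) for p in ref_phis])
        # an azimuthally symmetric model (e.g. the cylindrical start) gives
        # identical references, so azimuths are undetermined: align against
        # one reference and spread the assignments uniformly instead of
        # letting exact ties collapse every particle onto one view
        spread = np.abs(refs - refs[0]).max()
        degenerate = spread < 1e-2 * max(np.ptp(refs[0]), 1e-12)
        if degenerate:
            records = _fast_align_to_references(data, refs[:1], psis, cfg,
                                                ref_phis[:1], mask=score_mask)
            for i, r in enumerate(records):
                r.ref_index = i % len(ref_phis)
                r.phi = float(ref_phis[r.ref_index])
        else:
            records = _fast_align_to_references(data, refs, psis, cfg, ref_phis,
                                                mask=score_mask)
        psis = np.array([r.psi for r in records])
        new_assigned = np.array([r.ref_index for r in records])
        changed = float(np.mean(new_assigned != assigned))
        assigned = new_assigned
        mean_score = float(np.mean([r.score for r in records]))
        model = _reconstruct_from(stack, records, cfg)
        log_rows.append({"iteration": it, "mean_score": mean_score,
                         "changed_fraction": changed})
        prev_scores.append(mean_score)
        # early iterations can score high against an over-smooth model, so
        # only drops beyond 1% relative count as divergence
        tol = 0.01
        if (len(prev_scores) >= 3
                and prev_scores[-1] < prev_scores[-2] * (1 - tol)
                and prev_scores[-2] < prev_scores[-3] * (1 - tol)):
            reason = "divergence guard: mean score dropped twice"
            break
        if changed < cfg.min_changed_fraction:
            reason = "converged: assignment changes below threshold"
            break
    halves = None
    if cfg.halfset_mode:
        halves = reconstruct_halves(stack, records, cfg)
    return RefinementResult(volume=model, records=records,
                            log=pd.DataFrame(log_rows), halves=halves,
                            stopped_reason=reason)


def reconstruct_halves(stack: ParticleStack, records,
                       cfg: RefinementConfig) -> tuple[Volume3D, Volume3D]:
    """Two reconstructions from even/odd halves of the shuffled particle set."""
    rng = np.random.default_rng(cfg.halfset_seed)
    perm = rng.permutation(len(stack))
    return (_reconstruct_from(stack, records, cfg, indices=np.sort(perm[0::2])),
            _reconstruct_from(stack, records, cfg, indices=np.sort(perm[1::2])))


# --------------------------------------------------------------------------
# thresholds, mass-volume, model measurements


def mass_to_volume(mass_kda: float) -> float:
    """Protein volume (nm^3) from mass (kDa) at density 1.35 g/cm^3."""
    if mass_kda <= 0:
        raise ValueError("mass must be positive")
    return mass_kda * 1e3 / PROTEIN_DENSITY_DA_PER_A3 / 1e3


def volume_to_mass(volume_nm3: float) -> float:
    """Inverse of :func:`mass_to_volume`."""
    if volume_nm3 <= 0:
        raise ValueError("volume must be positive")
    return volume_nm3 * 1e3 * PROTEIN_DENSITY_DA_PER_A3 / 1e3


def iso_level_for_volume_fraction(volume: Volume3D, fraction: float,
                                  reference_volume: float) -> float:
    """Density level whose superlevel set fills ``fraction`` of a target volume.

    ``reference_volume`` is in nm^3 (typically from :func:`mass_to_volume`);
    the returned level is exact to one voxel's volume.  Larger fractions
    give lower (or equal) levels.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    voxel_nm3 = (volume.voxel_size / 10.0) ** 3
    target_vox = int(round(fraction * reference_volume / voxel_nm3))
    flat = volume.data.ravel()
    if target_vox > flat.size:
        raise ValueError("target volume exceeds the box")
    if target_vox < 1:
        return float(flat.max())
    return float(np.partition(flat, flat.size - target_vox)[flat.size - target_vox])


def axial_periodicity(volume: Volume3D, min_lag_vox: int = 5,
                      prominence: float = 0.05) -> float:
    """Repeat distance (nm) from the axial autocorrelation of the z profile.

    The mean in-plane density per z section is linearly autocorrelated
    (unbiased) and the first prominent nonzero peak is returned, refined by
    parabolic interpolation.
    """
    prof = volume.data.mean(axis=(1, 2)).astype(np.float64)
    prof = prof - prof.mean()
    nz = len(prof)
    ac = np.correlate(prof, prof, mode="full")[nz - 1:]
    ac = ac / np.maximum(nz - np.arange(nz), 1)  # unbiased
    ac = ac / ac[0]
    from scipy.signal import find_peaks
    peaks, _ = find_peaks(ac[:int(0.9 * nz)], prominence=prominence * np.ptp(ac))
    peaks = peaks[peaks >= min_lag_vox]
    if len(peaks) == 0:
        raise ValueError("no axial repeat detected")
    # sub-structure within the repeat (e.g. the interbead hump between
    # beads) produces minor ACF peaks below the fundamental; keep the first
    # peak whose height is comparable to the strongest one
    vmax = ac[peaks].max()
    peaks = peaks[ac[peaks] >= 0.5 * vmax]
    p = int(peaks[0])
    if 1 <= p < nz - 1:
        denom = ac[p - 1] - 2 * ac[p] + ac[p + 1]
        if denom != 0:
            p = p - 0.5 * (ac[p + 1] - ac[p - 1]) / denom
    return float(p * volume.voxel_size / 10.0)


def radial_profile(volume: Volume3D, z: int, r_step: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthally averaged density versus radius for one z section."""
    n = volume.shape[1]
    c = (n - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
    r = np.hypot(yy, xx).ravel()
    n_bins = int(np.ceil(n / 2.0 / r_step))
    idx = np.clip((r / r_step).astype(int), 0, n_bins - 1)
    sl = volume.data[z].astype(np.float64).ravel()
    sums = np.bincount(idx, weights=sl, minlength=n_bins)
    r_sums = np.bincount(idx, weights=r, minlength=n_bins)
    cnts = np.bincount(idx, minlength=n_bins)
    filled = cnts > 0
    # bin centers are the mean radius of the grid points actually in the bin
    return r_sums[filled] / cnts[filled], sums[filled] / cnts[filled]


def _fwhm_radius(centers: np.ndarray, prof: np.ndarray) -> float:
    """Radius where the profile first falls below half its maximum."""
    base = min(0.0, prof.min())
    p = prof - base
    half = p.max() / 2.0
    imax = int(p.argmax())
    below = np.nonzero(p[imax:] < half)[0]
    if len(below) == 0:
        return float(centers[-1])
    j = imax + below[0]
    r1, r2 = centers[j - 1], centers[j]
    v1, v2 = p[j - 1], p[j]
    return float(r1 + (v1 - half) / (v1 - v2) * (r2 - r1))


def max_diameter_fwhm(volume: Volume3D) -> float:
    """Maximum transverse diameter (nm): largest FWHM of the radial density
    profile over axial positions."""
    profiles = [radial_profile(volume, z) for z in range(volume.shape[0])]
    peak = max(p.max() for _, p in profiles)
    if peak <= 0:
        raise ValueError("volume has no positive density")
    best = 0.0
    for centers, prof in profiles:
        # skip weak sections where a half-max width is not meaningful
        if prof.max() < 0.5 * peak:
            continue
        best = max(best, 2.0 * _fwhm_radius(centers, prof))
    return best * volume.voxel_size / 10.0
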