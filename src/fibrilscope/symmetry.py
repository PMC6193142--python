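"""Region-masked sub-model refinement and rotational pseudo-symmetry scans.

The bead, arm and interbead regions of the repeat occupy fixed fractional
z-intervals; refining each region separately with a binary mask localizes
the alignment to that region, which overcomes axial flexibility of the
filament.  Rotational cross-correlation of a sub-model against its own
projections (or against aligned particles) reveals the rotational
symmetry orders present: an n-fold region correlates at every multiple of
360/n degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _geometry
from .core import CorrelationCurve, ParticleStack, Volume3D
from .match import masked_ncc_map
from .reconstruct import (RefinementConfig, RefinementResult,
                          project_about_axis, refine_projection_matching)

__all__ = [
    "RegionSpec",
    "default_regions",
    "region_mask",
    "extract_region",
    "refine_submodel",
    "rotational_correlation_scan",
    "detect_symmetry_orders",
]


@dataclass
class RegionSpec:
    """One axial region of the repeat.

    ``intervals`` are fractional z-intervals of the repeat in [0, 1); the
    arm region has two (it flanks the interbead on both sides).
    ``softness`` is the mask edge width in pixels (0 = binary).
    """

    name: str
    intervals: tuple
    softness: float = 0.0

    def __post_init__(self) -> None:
        if isinstance(self.intervals[0], (int, float)):
            self.intervals = (tuple(self.intervals),)
        for lo, hi in self.intervals:
            if not (0.0 <= lo < 1.0 and lo < hi <= 1.0):
                raise ValueError(f"invalid interval ({lo}, {hi})")
            if hi - lo <= 0:
                raise ValueError("empty region interval")


def default_regions() -> dict[str, RegionSpec]:
    """Bead / arm / interbead axial intervals of one repeat."""
    return {
        "bead": RegionSpec("bead", ((0.0, 0.30),)),
        "arm": RegionSpec("arm", ((0.30, 0.45), (0.85, 1.0))),
        "interbead": RegionSpec("interbead", ((0.45, 0.85),)),
    }


def _axial_weight(n_z: int, period_vox: float, region: RegionSpec,
                  z_offset: float = 0.0) -> np.ndarray:
    z = np.arange(n_z, dtype=float)
    frac = ((z - z_offset) / period_vox) % 1.0
    w = np.zeros(n_z)
    for lo, hi in region.intervals:
        inside = (frac >= lo) & (frac < hi)
        if region.softness > 0:
            soft_frac = region.softness / period_vox
            d = np.minimum((frac - lo) % 1.0, (hi - frac) % 1.0)
            ramp = np.clip(d / soft_frac, 0.0, 1.0)
            w = np.maximum(w, np.where(inside, 0.5 - 0.5 * np.cos(np.pi * ramp), 0.0))
        else:
            w[inside] = 1.0
    return w


def region_mask(shape: tuple, period_vox: float, region: RegionSpec,
                z_offset: float = 0.0) -> np.ndarray:
    """Binary (or soft) mask selecting a region's axial interval.

    ``shape`` may be 2D ``(n_z, n_x)`` for reference images or 3D
    ``(n_z, n_y, n_x)`` for volumes; the 2D mask is the projection support
    of the 3D one (both depend on z only).
    """
    w = _axial_weight(shape[0], period_vox, region, z_offset)
    out = np.broadcast_to(w.reshape((-1,) + (1,) * (len(shape) - 1)), shape)
    if region.softness == 0:
        return np.ascontiguousarray(out) > 0.5
    return np.ascontiguousarray(out)


def extract_region(volume: Volume3D, period_vox: float, region: RegionSpec,
                   z_offset: float = 0.0) -> Volume3D:
    """Window a volume to a region's axial interval (zero outside)."""
    mask = region_mask(volume.shape, period_vox, region, z_offset)
    return Volume3D(volume.data * mask, volume.voxel_size)


def refine_submodel(stack: ParticleStack, init: Volume3D, region: RegionSpec,
                    cfg: RefinementConfig, period_vox: float,
                    records=None, z_offset: float = 0.0) -> RefinementResult:
    """Projection-matching refinement with alignment localized to a region.

    Identical to :func:`refine_projection_matching` except the alignment
    scoring uses the masked NCC with the region's 2D mask (fixed in the
    reference frame), and the returned volume is windowed to the region's
    axial interval.
    """
    mask2d = region_mask((stack.box[0], stack.box[1]), period_vox, region,
                         z_offset)
    if region.softness > 0:
        mask2d = mask2d > 0.5
    res = refine_projection_matching(stack, init, cfg, records=records,
                                     score_mask=mask2d)
    res.volume = extract_region(res.volume, period_vox, region, z_offset)
    return res


def rotational_correlation_scan(model: Volume3D, increment: float = 5.0,
                                data: ParticleStack | None = None,
                                records=None,
                                mask: np.ndarray | None = None) -> CorrelationCurve:
    """Correlation of model projections versus rotation about the axis.

    Self mode (``data=None``): for each offset angle on the grid, the mean
    normalized correlation between projections at azimuth phi and
    phi + offset over a full phi grid.

    Data mode: for each particle, the masked NCC between the (in-plane
    aligned) particle and the model projection at its assigned azimuth plus
    the offset; the curve is the mean over particles.  Requires records.
    """
    if 360.0 % increment:
        raise ValueError("increment must divide 360")
    angles = np.arange(0.0, 360.0, increment)
    n_ang = len(angles)
    projs = np.stack([project_about_axis(model, a) for a in angles])

    if data is None:
        flat = projs.reshape(n_ang, -1)
        if mask is not None:
            flat = flat[:, np.asarray(mask).astype(bool).ravel()]
        flat = flat - flat.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(flat, axis=1)
        norms[norms == 0] = 1.0
        flat = flat / norms[:, None]
        gram = flat @ flat.T
        values = np.array([np.mean([gram[i, (i + k) % n_ang] for i in range(n_ang)])
                           for k in range(n_ang)])
        return CorrelationCurve(angles, values)

    if records is None:
        raise ValueError("data mode requires alignment records")
    from .match import invert_record
    if mask is None:
        mask = np.ones(projs.shape[1:], dtype=bool)
    mask = np.asarray(mask).astype(bool)
    values = np.zeros(n_ang)
    for img, rec in zip(data.data, records):
        aligned = invert_record(img.astype(np.float64), rec)
        for k in range(n_ang):
            phi = (rec.phi + angles[k]) % 360.0
            ref = projs[int(round(phi / increment)) % n_ang]
            surface = masked_ncc_map(aligned, ref, mask)
            values[k] += float(surface[0, 0])
    values /= len(data)
    return CorrelationCurve(angles, values)


def detect_symmetry_orders(curve: CorrelationCurve,
                           prominence: float = 0.1) -> list[tuple[int, np.ndarray]]:
    """Candidate rotational symmetry orders from a correlation curve.

    Peaks are local maxima on the circular angle grid with prominence at
    least ``prominence`` times the curve range.  An order n is reported
    when peaks occur within one grid step of every nonzero multiple of
    360/n.  Orders are returned in decreasing n with their peak angles.
    """
    from scipy.signal import find_peaks
    vals = curve.values
    if np.ptp(vals) < 1e-12:
        return []
    step = curve.step
    n_ang = len(vals)
    # wrap the curve so peaks at/near 0 and 360 are handled circularly
    ext = np.r_[vals[-n_ang // 4:], vals, vals[: n_ang // 4]]
    pk, _ = find_peaks(ext, prominence=prominence * np.ptp(vals))
    pk = pk - n_ang // 4
    peak_angles = np.sort(np.unique((pk % n_ang) * step))
    peak_angles = peak_angles[peak_angles > 0]
    if len(peak_angles) == 0:
        return []
    orders = []
    for n in range(int(360.0 / (2 * step)), 1, -1):
        mults = 360.0 * np.arange(1, n) / n
        ok = all(np.min(np.abs(((peak_angles - m + 180) % 360) - 180)) <= step + 1e-9
                 for m in mults)
        if ok:
            near = [peak_angles[np.argmin(np.abs(((peak_angles - m + 180) % 360) - 180))]
                    for m in mults]
            orders.append((n, np.array(near)))
    return orders
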