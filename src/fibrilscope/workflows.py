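"""High-level recovery experiments on synthetic phantoms.

Each function builds a phantom with the measured default parameters,
runs the relevant part of the analysis from scratch, and returns the
recovered quantities.  These are the package's headline demonstrations:
the projection-matching pipeline recovering the repeat geometry, the
rotational scans locating symmetry peaks, and the tomogram / serial-
section morphometry recovering packing and diameter statistics.
"""

from __future__ import annotations

import numpy as np

from . import morphometry, phantoms, preprocess, reconstruct, symmetry
from .match import align_stack_iterative

__all__ = [
    "single_particle_recovery",
    "symmetry_scan_angles",
    "tomogram_morphometry",
    "fiber_stack_measurement",
]


def single_particle_recovery(n_particles: int = 400, box_px: int = 128,
                             voxel_size: float = 8.0, snr: float = 0.3,
                             shift_max: float = 8.0, seed: int = 0,
                             n_iterations: int = 5, azimuth_step: float = 5.0,
                             symmetry_order: int = 2,
                             prealign_iters: int = 5,
                             prealign_psi_step: float = 10.0) -> dict:
    """Full single-particle pipeline on the default repeat phantom.

    Simulates projections with random azimuths, in-plane rotations and
    shifts at the given SNR; preprocesses, 2D-aligns, builds the
    cylindrical initial model and refines by projection matching with the
    given symmetry; measures the repeat distance (axial autocorrelation)
    and the maximum diameter (widest radial-profile FWHM) of the final
    model in nm.
    """
    spec = phantoms.PhantomSpec()
    volume = phantoms.make_microfibril_phantom(spec, box_px, voxel_size)
    stack, _truth = phantoms.make_projection_dataset(
        volume, n_particles, snr=snr, shift_max=shift_max, seed=seed)
    pstack = preprocess.preprocess_stack(stack)
    records, _ = align_stack_iterative(pstack, n_iter=prealign_iters,
                                       psi_step=prealign_psi_step,
                                       shift_max=int(shift_max))
    records, average, _ = reconstruct.verticalize_records(pstack, records)
    init = reconstruct.cylindrical_initial_model(average, voxel_size)
    cfg = reconstruct.RefinementConfig(azimuth_step=azimuth_step,
                                       n_iterations=n_iterations,
                                       symmetry_order=symmetry_order,
                                       shift_max=int(shift_max))
    result = reconstruct.refine_projection_matching(pstack, init, cfg,
                                                    records=records)
    return {
        "periodicity_nm": reconstruct.axial_periodicity(result.volume),
        "max_diameter_nm": reconstruct.max_diameter_fwhm(result.volume),
        "phantom": volume,
        "model": result.volume,
        "records": result.records,
        "log": result.log,
    }


def symmetry_scan_angles(box_px: int = 96, voxel_size: float = 8.0,
                         increment: float = 5.0) -> dict:
    """Peak angles of the rotational self-correlation scans.

    Returns the nonzero-angle maximum of the two-fold-symmetrized default
    phantom's scan (expected at 180 degrees) and the smallest positive
    local-maximum angle of the eight-fold interbead scan (expected at 45).
    """
    spec2 = phantoms.PhantomSpec()
    vol2 = reconstruct.impose_cn(
        phantoms.make_microfibril_phantom(spec2, box_px, voxel_size), 2)
    curve2 = symmetry.rotational_correlation_scan(vol2, increment)
    nonzero = curve2.angles > 0
    c2_angle = float(curve2.angles[nonzero][np.argmax(curve2.values[nonzero])])

    spec8 = phantoms.PhantomSpec(axial_symmetry_order=8)
    vol8 = phantoms.make_microfibril_phantom(spec8, box_px, voxel_size)
    period_vox = spec8.periodicity * 10.0 / voxel_size
    interbead = symmetry.extract_region(vol8, period_vox,
                                        symmetry.default_regions()["interbead"])
    curve8 = symmetry.rotational_correlation_scan(interbead, increment)
    orders = symmetry.detect_symmetry_orders(curve8)
    if not orders:
        raise RuntimeError("no symmetry detected in the C8 interbead scan")
    peak_angles = np.sort(np.unique(np.concatenate([a for _, a in orders])))
    c8_angle = float(peak_angles[0])
    return {"c2_peak_deg": c2_angle, "c8_first_peak_deg": c8_angle,
            "c2_curve": curve2, "c8_curve": curve8}


def tomogram_morphometry(box: int = 200, voxel_size: float = 1.0,
                         seed: int = 1, n_filaments: int = 60) -> dict:
    """Trace a packed-filament phantom and recover packing statistics.

    Filaments are traced from one seed point per true filament (the
    centerline midpoint); spacing, diameter and axial repeat period are
    then measured from the traced filaments only.
    """
    spec = phantoms.TomogramPhantomSpec(n_filaments=n_filaments)
    volume, truth = phantoms.make_tomogram_phantom(spec, box, voxel_size,
                                                   seed=seed)
    seeds = [t.points[len(t) // 2] for t in truth]
    traces = morphometry.trace_filaments(volume, seeds)
    traces = [t for t in traces if len(t) >= 2]
    table, summary = morphometry.orientation_and_spacing(traces)
    diameters, periods = [], []
    for tr in traces:
        d, p = morphometry.filament_geometry(volume, tr)
        diameters.append(d)
        if p is not None:
            periods.append(p)
    return {
        "n_traced": len(traces),
        "mean_spacing_nm": summary["mean_nn_distance_nm"],
        "mean_diameter_nm": float(np.mean(diameters)),
        "mean_period_nm": float(np.mean(periods)) if periods else None,
        "orientation_table": table,
    }


def fiber_stack_measurement(seed: int = 3, n_fibers: int = 300,
                            sampling_interval: int = 100) -> dict:
    """Measure a synthetic serial-section fiber stack end to end.

    Generates contours at every ``sampling_interval``-th slice, fits an
    ellipse to each and summarizes the minor diameters.
    """
    spec = phantoms.FiberStackSpec(n_fibers=n_fibers)
    contours, truth = phantoms.make_fiber_sections(
        spec, seed=seed, slices=range(0, spec.n_slices, sampling_interval))
    fits = morphometry.fit_contour_table(contours, spec.pixel_size)
    _, summary = morphometry.fiber_diameter_summary(fits, sampling_interval)
    return {
        "mean_diameter_um": summary["mean_um"],
        "sd_diameter_um": summary["sd_um"],
        "n_measurements": summary["n_measurements"],
        "truth_mean_um": float(truth.diameter_um.mean()),
    }
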