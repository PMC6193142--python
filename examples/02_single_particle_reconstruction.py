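"""Reconstruct the repeat from noisy 2D projections.

Simulates a boxed-particle dataset (random azimuths, in-plane rotations
and shifts, SNR 0.3), then runs the full pipeline: preprocessing,
reference-free 2D alignment, cylindrical initial model, and iterative
projection matching with C2 imposed.  Takes a couple of minutes.
"""

from fibrilscope.workflows import single_particle_recovery

out = single_particle_recovery(n_particles=200, box_px=96, snr=0.3,
                               shift_max=6.0, seed=0, n_iterations=4)

print(out["log"].to_string(index=False))
print(f"recovered repeat distance: {out['periodicity_nm']:.2f} nm "
      "(phantom: 59.2 nm)")
print(f"recovered max diameter:    {out['max_diameter_nm']:.2f} nm "
      "(phantom: 20.8 nm)")
print("The axial autocorrelation of the refined model locates the bead-to-"
      "bead repeat; the widest radial-profile FWHM gives the bead diameter.")
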