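"""Trace filaments in a packed-bundle phantom and measure the packing.

A tomogram-like volume of ~50 beaded filaments (30 nm center spacing,
11.4 nm diameter, 60 nm repeat) is traced from seed points; spacing,
diameter and axial period are then measured from the traces alone.
"""

from fibrilscope.workflows import tomogram_morphometry

out = tomogram_morphometry(box=200, voxel_size=1.0, seed=1)

print(f"filaments traced:        {out['n_traced']}")
print(f"mean center spacing:     {out['mean_spacing_nm']:.2f} nm (target 30)")
print(f"mean filament diameter:  {out['mean_diameter_nm']:.2f} nm (target 11.4)")
print(f"mean axial repeat:       {out['mean_period_nm']:.2f} nm (target 60)")
print("Spacing is the perpendicular center-to-center distance to the "
      "nearest neighboring trace; diameter is the FWHM of the mean radial "
      "intensity profile.")
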