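# fibrilscope

Single-particle averaging, 3D reconstruction, symmetry analysis and
morphometry of beaded extracellular filaments — fibrillin microfibrils in
particular — implemented as a pure-Python library with synthetic phantom
generators for every input.

Fibrillin microfibrils are ~12–20 nm wide beads-on-a-string filaments
with a ~56–60 nm axial repeat that form the micrometer-scale zonule
fibers suspending the eye's lens.  Their repeating unit can be
reconstructed in 3D from negative-stain TEM projection images of boxed
repeats, and their tissue-scale organization measured in electron
tomograms and serial block-face SEM stacks.  This package implements
that whole analysis chain:

* **Preprocessing** — CTF phase flipping, edge-mean normalization and a
  600 Å / 20 Å top-hat band-pass.
* **Alignment** — masked, locally normalized cross-correlation (FFT
  accelerated, exact against direct computation), exhaustive 2D particle
  alignment and reference-free iterative averaging.
* **Reconstruction** — cylindrical initial model from a class average,
  projection at arbitrary azimuth about the filament axis, weighted
  back-projection for both filament geometry and single-axis tilt
  series, Cn symmetry imposition, and an iterative projection-matching
  refinement loop with a divergence guard.
* **Symmetry** — bead / arm / interbead region masks, region-localized
  sub-model refinement, and rotational cross-correlation scans whose
  peaks reveal rotational (pseudo-)symmetry orders: a two-fold filament
  correlates at 180°, an eight-fold interbead at every 45° multiple.
* **Validation** — Fourier shell correlation between half-set
  reconstructions with the resolution quoted at FSC = 0.5, and a
  reference-free classifier (PCA + k-means) for class-average
  diagnostics.
* **Morphometry** — structure-tensor filament tracing, relative
  orientation and nearest-neighbor spacing of packed filaments, FWHM
  diameters and axial repeat periods along traces, and serial-section
  fiber diameters via direct least-squares ellipse fits (the minor axis
  of an obliquely sectioned cylinder equals its true diameter).
* **Phantoms** — seed-deterministic generators for the beaded repeat
  volume, noisy projection datasets, packed-filament tomogram volumes,
  single-axis tilt series with a missing wedge, and elliptical fiber
  cross-section stacks, all with recorded ground truth.  Generator
  defaults encode the measured microfibril values (59.2 nm repeat,
  20.8 nm maximum diameter, four arms, eight chains with two-fold axial
  symmetry, 30 nm center spacing, 11.4 nm filament diameter, 60 nm
  tomogram repeat, 2.06 ± 1.40 μm fiber diameters).

## Worked example

`examples/02_single_particle_reconstruction.py` simulates 200 noisy
projection images of the repeat phantom (SNR 0.3, random azimuths,
rotations and shifts), runs the full pipeline, and measures the refined
model:

```
 iteration  mean_score  changed_fraction
         0    0.603664             1.000
         1    0.634495             0.015
recovered repeat distance: 59.44 nm (phantom: 59.2 nm)
recovered max diameter:    21.11 nm (phantom: 20.8 nm)
```

The mean alignment score rises as the model sharpens and the loop stops
once fewer than 2% of azimuth assignments change.  The repeat distance
is the first strong peak of the model's axial autocorrelation; the
maximum diameter is the widest full-width-at-half-maximum of its radial
density profile — both recovered within ~1.5% of the phantom's ground
truth.  The other example scripts cover the phantom itself, symmetry
scans, tomogram morphometry, fiber diameters and the missing-wedge
effect.

There is also a thin command-line interface (`fibrilscope simulate |
preprocess | align | reconstruct | submodel | symscan | fsc | tomo |
track | fibers | demo`); `fibrilscope demo --out DIR` runs the whole
synthetic pipeline into a directory with a checksummed manifest.

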