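# Methods

This note documents the models, conventions and design choices behind
fibrilscope, in the spirit of a methods section: what is computed, under
which assumptions, and where the free choices were made.

## Conventions

Volumes are `(z, y, x)` rasters with the filament axis along z and an
isotropic voxel size in Å; projection images are `(z, x)` with the
filament vertical.  Angles are degrees.  The azimuth φ is the rotation
of the repeat about its own axis — the unknown orientation parameter in
filament single-particle analysis; ψ is the in-plane rotation of a
boxed particle.  A particle is modeled generatively as
`shift(rotate_inplane(projection(volume, φ), ψ), (Δx, Δy))`, and every
record stores the parameters in that convention.  Projection follows
the Radon-transform angle convention that `skimage.transform.iradon`
inverts; this pairing is what guarantees the reconstruction has the
same hand as the phantom (verified by a chirality test with a random
asymmetric volume — an easy convention to get silently wrong, because
mirror-symmetric test objects cannot detect it).

Density is protein-positive throughout.  Negative-stain contrast
inversion is not simulated: after normalization the sign is a pure
convention, and keeping one sign everywhere avoids a parallel code
path.

## The repeat phantom

One repeat (default 59.2 nm) is partitioned axially into bead
(fractions 0–0.30), arm (0.30–0.45 and 0.85–1.0) and interbead
(0.45–0.85) regions with raised-cosine axial envelopes.  The bead is a
soft-edged solid disk whose azimuthally averaged profile crosses half
maximum at half the maximum diameter (20.8 nm default), so the
"maximum diameter" measurement recovers the parameter by construction.
The interbead is a hollow bundle of four strands (Gaussian radial shell
at half the interbead diameter, localized angular bumps); the arms are
strand bundles at intermediate radii.

Two deliberate asymmetries matter:

* **Axial polarity.** The bead density ramps along its own axis, the
  two arm bands have different amplitudes and the interbead tapers.
  Projections therefore distinguish the two filament ends.  This
  mirrors the strongly asymmetric banding of the real repeat and is
  load-bearing: with a weakly polar phantom, per-particle polarity
  cannot be resolved at SNR 0.3 and the reconstruction mixes the two
  ends of the filament.
* **Exact rotational symmetry.** All angular factors are built from
  even Chebyshev combinations of the unit direction vector
  (cos 2θ = (x²−y²)/r² and recurrences), which are bitwise invariant
  under the exact 180° grid rotation.  The imposed Cn symmetry is
  therefore exact to machine precision, not just to interpolation
  tolerance.

The projection-dataset generator draws azimuths uniformly on
[0°, 360°), in-plane rotations uniformly (the orientation of a boxed
repeat in a micrograph is arbitrary), shifts uniformly within ±8 px,
and adds white Gaussian noise with variance = signal variance / SNR.
The default SNR of 0.3 is a free choice (micrograph noise levels are
not part of the encoded measurements); it is low enough that single
particles are visibly dominated by noise yet class averages are clean.

## Preprocessing

Order is fixed: phase flip (when CTF parameters are supplied), then
edge-mean normalization, then band-pass.  The CTF is
`CTF(k) = sqrt(1−A²)·sin χ + A·cos χ` with
`χ = πλΔz k² − (π/2) Cs λ³ k⁴`, underfocus Δz > 0 (printed negative
defocus values map to positive Δz), amplitude contrast A = 0.10 by
default.  The sign is chosen positive at low frequency so that an image
whose band lies entirely before the first zero is untouched by phase
flipping.  Phase flipping multiplies Fourier coefficients by the CTF's
sign, leaves DC alone, and is an exact involution.  The band-pass is a
hard (top-hat) annulus from 1/600 to 1/20 Å⁻¹; hard edges ring, but
they are kept deliberately as the simplest faithful filter.  Whether
normalization precedes filtering is not observable downstream (both are
linear); the fixed order is a convention.

## Masked correlation and alignment

`masked_ncc_map` computes, at every offset, the Pearson correlation
between template and image patch restricted to a binary mask, with the
local mean and variance taken under the mask.  It is evaluated with
five FFT correlations (numerator, mask sums, and masked second moment)
and matches a direct double loop to better than 1e−5; offsets with
vanishing local variance score 0.

`align_particle` searches (reference, ψ grid, integer shifts) and
refines the correlation peak by separable parabolic interpolation —
without sub-pixel refinement, the shift quantization in the rotated
frame couples into a one-grid-step ψ bias.  Rotations are applied to
the particle; references stay pristine.  Ties break deterministically:
lowest reference index, smallest ψ, smallest shift.

The reference-free pre-alignment stage iterates "align everything to
the running average" five times (full 0–360° ψ search).  It converges
to a consistent in-plane frame up to a global rotation and a global
polarity: the evolving average is a polarity mixture, so individual
particles may sit 180° flipped.  Both ambiguities are handled
downstream — the average is straightened to vertical via its intensity
principal axis, and the 3D refinement searches ψ and ψ+180° so the
model polarizes over iterations.

## Reconstruction and refinement

Weighted back-projection is `skimage.transform.iradon` (ramp filter,
linear interpolation) applied slice-by-slice perpendicular to the
rotation axis: per z slice for the filament geometry, per y slice for
single-axis tilt series.  Particles sharing an assigned azimuth are
averaged first so each distinct view enters with equal weight.  The
cylindrical initial model back-projects the straightened class average
replicated over a dense azimuth grid and then azimuthally averages the
result, making the start exactly rotationally symmetric.

The refinement loop per iteration: project the model over the
symmetry-reduced azimuth grid (default 5°), align every particle to
every reference (local ψ window ±10° plus the 180° flip, shifts within
±8 px by circular FFT correlation with masked normalization),
reconstruct, impose Cn (flip-based and exact for right angles), and
low-pass to 20 Å.  Stopping: the iteration budget, fewer than 2% of
azimuth assignments changing, or a divergence guard that fires when the
mean score drops by more than 1% on two consecutive iterations (smaller
dips are normal — an over-smooth cylindrical start scores deceptively
high).

Two non-obvious details:

* **Degenerate starts.**  When every reference is (numerically) the
  same — the cylindrical init — azimuths are undetermined and exact
  ties would collapse all particles onto one view.  The loop detects
  this and spreads assignments uniformly instead.
* **Score centering.**  The component of the model common to every
  azimuth (most of a filament's mass) attracts all particles to
  whichever reference happens to carry most of it.  Assignments are
  therefore made on the score matrix centered per reference
  (subtracting each reference's mean score over particles), which makes
  the choice sensitive to the particle-specific azimuthal differences.
  Logged scores remain the raw correlations.

Known limitation: the azimuthal structure of a filament at 20 Å is a
few percent of the masked variance, so the per-5° score contrast is of
the same order as the score perturbations caused by back-projection
artifacts.  Azimuth assignments consequently jitter by roughly ±10°
even on noise-free data, azimuthal detail is smeared, and the
noise-free model/phantom correlation plateaus near 0.86 rather than
approaching 1 — consistent with the general experience that filament
models at this resolution degrade without imposed symmetry.  Axial
quantities (repeat distance, diameter) are insensitive to this and are
recovered within ~1%.

Half-set models for FSC split the particles even/odd after a shuffle
with a fixed seed.  `mass_to_volume` uses a protein density of
1.35 g/cm³ (0.813 Da/Å³), giving ≈ 3.1 × 10³ nm³ for a 2500 kDa repeat.

## Region sub-models and symmetry scans

Regions are fractional z-intervals of the repeat (bead 0–0.30, arm
0.30–0.45 ∪ 0.85–1.0, interbead 0.45–0.85 — read qualitatively from
the labeled banding; no numeric boundaries are published).  Sub-model
refinement is the same loop with scoring masked to the region's 2D
projection support; with the full-repeat region it reduces exactly to
the unmasked refinement.  Self-mode rotational scans correlate model
projections at φ and φ+Δ over a full φ grid; data-mode scans correlate
aligned particles against projections at their assigned azimuth plus Δ
(records' azimuths are grid-aligned after projection matching).
Symmetry orders are reported when peaks (local maxima with ≥ 0.1 ×
curve-range prominence) appear within one grid step of every nonzero
multiple of 360/n; nesting (8 → 4 → 2) is expected and real.

## Morphometry

Filament tracing steps along the local structure-tensor ridge direction
(the eigenvector with the smallest eigenvalue — intensity varies least
along the tube axis), re-centering each step on the perpendicular
intensity centroid, and stops at the volume edge or when local contrast
falls below 25% of the 99th percentile.  Spacing takes, per filament,
the nearest point of each neighboring trace and projects out the axial
component using the filament's mean tangent (per-sample tangents are
too noisy: projecting with them before the minimum biases the distance
low).  Relative orientation is measured against the bundle principal
direction, the leading eigenvector of the summed tangent outer
products; the generator's "orientation dispersion" is recovered as the
r.m.s. relative angle.  Diameter is the FWHM of the mean perpendicular
radial profile after subtracting the far-field baseline (neighbor
contamination); the axial period is the first strong autocorrelation
peak of the intensity sampled along the trace, with sub-structure peaks
below half the height of the strongest peak ignored (the same rule used
for the model's axial repeat, where the bead–interbead alternation adds
a weak half-period peak).

Fiber contours are fitted with the direct least-squares ellipse fit
(scikit-image's `EllipseModel`), with explicit rejection of collinear
and degenerate inputs; the minor diameter of an obliquely sectioned
circular cylinder equals the true diameter, which is the whole point of
fitting ellipses rather than measuring apparent widths.  Summaries keep
one measurement per fiber per sampling interval (default every 100
slices) and histogram at 0.5 μm bins.

The fiber-diameter generator draws true diameters from a normal
truncated at 0.1 μm whose location and scale are solved jointly so the
*post-truncation* mean and S.D. equal the targets (2.06, 1.40 μm) —
naively plugging the targets in as (loc, scale) would inflate the
realized mean by ~11%.

The tomogram phantom packs filaments on a jittered hexagonal lattice
(jitter 2% of the spacing; larger jitter biases the
nearest-of-six-neighbors distance noticeably below the lattice
constant), with Gaussian tube cross-sections (FWHM = the diameter
parameter) and raised-cosine beading.  Meshwork mode tilts each
filament by a folded-normal polar angle with uniform azimuth, so the
r.m.s. tilt equals the dispersion parameter.

## What the phantoms do and do not show

The generators emulate geometry, orientation ambiguity, shift jitter
and white noise.  They do not simulate stain granularity, carbon
support, radiation damage, structural heterogeneity beyond the imposed
flexibility of separate regions, or SBF-SEM charging.  Passing the
recovery tests therefore demonstrates that the algorithms are correct
and self-consistent at realistic noise levels and geometry — not that
they would reach any particular resolution on real micrographs.  The
resolution printed for the synthetic demo (FSC 0.5 between half-sets)
reflects the phantom, particle count and noise level, and is not
comparable to values measured on real data.

## Problem sizes

Default experiment sizes were chosen to represent the method honestly
at desk scale: 128-px boxes at 8 Å/voxel for the repeat phantom (one
full repeat is 74 voxels), 400 particles for the headline recovery run,
200³ voxels at 1 nm for the tomogram phantom (~50 filaments), and 300
fibers sampled every 100 of 1500 slices.  Reported statistics at these
sizes carry a few percent of sampling noise; the mean fiber diameter in
particular has a standard error of ~4% at 300 fibers.
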