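# Methods

This note records the models, defaults and design decisions behind
`nanovssa`, in the order the pipeline runs.

## Phantoms and ground truth

Particles are unions of implicit primitives (spheres and capsules) with a
signed-distance representation, rasterised to a voxel grid with unit
interior density and 3×3×3 subvoxel anti-aliasing in a one-voxel band
around the boundary.  Unit density is adequate for homogeneous metal or
silica particles under mass-thickness contrast.  Three classes emulate the
specimens this workflow is used on:

* **sphere** — colloidal gold, default 20 nm diameter: the validation
  control, with analytic truth 4πr², 4/3πr³.
* **branched** — a core sphere (default 30 nm) plus capsule spikes
  (length 10 nm, radius 3 nm) in seeded uniform directions, giving an
  overall extent of ~50 nm.  The spike parameterisation is a modelling
  choice: it is analytically tractable and exposes a tunable count of
  surface extensions.
* **aggregate** — silica-like aggregates grown by a seeded random walk:
  each new subunit (diameter drawn from a range, default 8–20 nm) attaches
  to a random existing subunit at centre distance 0.8 × (sum of radii).
  The 0.8 overlap factor guarantees 26-connectivity with visible necks.

Truths for non-analytic classes come from isosurface metrology (the
`surface` module) on the signed-distance field sampled at 4× finer voxels,
so truth and pipeline measurement never share a code path at the same
resolution.

**Field placement** defaults to a *monolayer*: centres within ±4 nm of the
central plane and, while the packing allows, pairwise separation enforced
in the beam-projected (y, x) plane.  This emulates colloids dried on a
support film, where projected superposition of discrete particles is rare.
When a field is too crowded for a monolayer (more than ~6–7 particles of
~20 nm in a 96³ nm box), particles are stacked in depth with 3D separation
only, choosing the candidate position whose projection overlaps least.
Placement margins (6 voxels radially beyond the field-of-view cylinder,
9 voxels along the tilt axis) keep reconstructed particles clear of the
volume border under jitter and streaks; they are the loosest margins with
no placement failures over hundreds of crowded draws.

## Acquisition model

Projection images are line integrals of density along the beam after
rotating the specimen about the y axis (the tilt axis), computed by a
precomputed sparse matrix of bilinear interpolation footprints shared by
all y slices.  Values are kept in "thickness space" (nm × density) so
reconstruction stays linear.  Defaults: ±65° at 1° increments — the
routine single-axis geometry with its missing wedge.  At 0° the sampling
grid coincides with the voxel grid, so the zero-tilt image is an exact
axis-aligned sum (used by several tests).

Noise follows the bright-field intensity model I = dose·exp(−p/λ),
Poisson-sampled plus optional Gaussian readout noise, then converted back
to thickness.  Dose defaults to 2000 counts per pixel through vacuum.  The
attenuation constant defaults to **λ = 100 nm**: gold and silica are
strong mass-thickness scatterers, and λ = 100 nm gives a 20 nm particle
~18% bright-field contrast — enough that a single particle can be
localised to a fraction of a pixel, which is also the regime in which
cross-correlation alignment of real data operates.  (At λ = 300 nm the
contrast of a 20 nm particle drops to ~6% and single-particle alignment
becomes photon-limited beyond the Cramér–Rao bound for sub-half-pixel
registration.)  Stage jitter is a seeded uniform translation of up to
3 px per image, recorded as ground truth for the alignment stage.

## Alignment

Each image is registered to its lower-|angle| neighbour by normalised
cross-correlation (Hann-windowed, soft band-pass pre-filter of Gaussian
sigmas 1/10 px); corrections accumulate outward from the zero-tilt anchor
and the rounds repeat until the mean update falls below 0.5 px (default,
max 10 rounds).  Only shifts relative to the anchor are observable; a
global translation of the whole series is gauge freedom and harmless to
reconstruction.  The correlation peak is refined by a local 16× upsampled
DFT of the cross-power spectrum followed by a parabolic fit on the fine
grid — integer-grid parabolic fits alone pixel-lock at ~0.15 px per pair,
which a 131-image neighbour chain cannot afford.

**Tilt-axis offset.**  Rotating about an axis displaced by *o* px from the
image centre shifts every projection by o(1−cos θ) along x.  For parallel
beams this is almost degenerate with per-image translations, so
reconstruction-quality scans (streak/negativity energy, data-consistency
residuals) are nearly flat in *o*; instead the offset is estimated by
least-squares fitting the o(1−cos θ) signature to the cross-correlation
shift curve, with sin θ (specimen depth) and constant (anchor gauge)
nuisance terms.  On synthetic data with a 3 px offset the fit recovers
2.8 px, within the half-pixel target; the residual underestimate comes
from the window-induced multiplicative bias of pairwise registration.

## Reconstruction

All three algorithms share the acquisition's sparse projector, so the
back-projector is the exact adjoint of the forward model — the matched
pair SIRT needs for stable convergence.

* **WBP**: frequency-domain ramp along x with raised-cosine rolloff from
  0.9× Nyquist, back-projection scaled by π/(2·n_angles).
* **SIRT** (default, 15 iterations, relaxation 1.0): x ← x + relax·C⁻¹Aᵀ
  R⁻¹(b − Ax) with diagonal row/column-sum normalisation and zero
  initialisation, so one iteration is a normalised back-projection.  On
  noise-free data the projection residual decreases strictly.  At the
  default 15 iterations a noise-free full-range sphere reconstructs with
  voxel correlation ~0.965 against the phantom (~0.98 needs ~30
  iterations); the default follows the 10–20 iteration practice for
  bright-field series, where SIRT's superior noise behaviour — its SNR
  beats WBP's on the noisy ±65° benchmark — matters more than asymptotic
  sharpness.
* **ART**: damped block-Kaczmarz sweeps (relaxation 0.25) per tilt image
  in angle order; deterministic.

`reconstruction_quality` reports voxelwise Pearson correlation, SNR in dB
after affine intensity matching (capped at 99 dB), and the z/x extent
ratio of the largest half-max component — the missing-wedge elongation,
which grows monotonically as the tilt range shrinks (±50° > ±65° > ±90°).

## Segmentation

The primary rule is the **histogram valley**: the threshold sits at the
minimum of the smoothed grey-value histogram (256 bins, 5-bin moving
average) between its two dominant modes.  Mode detection ranks local
maxima by prominence on the log-count scale with a minimum-count floor;
particle voxels are typically ≪1% of a reconstruction, so ranking by raw
counts would latch onto noise ripples of the background lobe.  The valley
itself (argmin between the modes, ties toward the lower grey value) is
unaffected by the monotone log transform.

Sparse or strongly blurred fields can be genuinely unimodal — a single
~17 nm particle contributes only a few hundred downsampled voxels, too few
to form a mode.  The pipeline then falls back to a **relative-maximum
rule**: threshold at 0.64 × the 99.9th-percentile grey value, the median
relative level the valley rule selects on resolved fields.  Valley picks
outside a 0.45–0.75 × robust-max plausibility band are treated the same
way.  The goal is a single consistent measuring rule across a study, so
rank-based validation statistics are not scrambled by estimator switching.
Otsu's criterion is available as an explicit alternative.

Surface smoothing is the 2×2×2 block average (voxel size doubles), applied
before thresholding and meshing by default to tame missing-wedge streaks.
Components are 26-connected (6 optional), border-touching components are
excluded, and components under 30 voxels are despeckled.

## Surface metrology

Marching cubes with topologically disambiguated case tables guarantees
watertight meshes; each labelled particle is meshed on its own 2-voxel-
padded bounding box.  Area is the sum of half cross-product magnitudes;
volume the divergence-theorem sum of signed tetrahedra (translation-
invariant, orientation taken by absolute value); both are cross-checked
against trimesh and against a voxel-counting oracle in the tests.  VSSA
uses the unit identity 1 nm⁻¹ = 1000 m²/cm³; the >60 m²/cm³ nanostructure
classification is returned alongside.  No mesh-level smoothing is applied:
the only smoothing in the pipeline is the voxel-space block average above.

A published worked example with totals 13 895 nm² and 38 763 nm³ prints a
VSSA of 332 m²/cm³; the ratio of those numbers is 358.5 m²/cm³.  The two
are arithmetically inconsistent; this package computes the ratio, and the
acceptance guard asserts 358.5, not 332.

## 2D validation (projected metrics)

The zero-tilt image is segmented (8-connected, border-excluded,
despeckled) and each region yields the equivalent circle diameter
ECD = 2√(A/π), sphere-formula area and volume (r = ECD/2), and sphericity
(√(λ_min/λ_max) of the second-central-moment matrix; 1 for a disk, 0.5
for a 2:1 ellipse).  The default threshold is the **background floor**
(median + 3 robust sigma of the lightly smoothed image, Gaussian σ = 1 px)
rather than Otsu: a projected sphere is a thickness dome falling
continuously to zero at its rim, so Otsu lands mid-dome and erodes the
ECD by 5–8%, while the floor rule recovers the silhouette to ~±0.5 px.
Particles that superimpose in projection merge into one region — the
inherent 2D limitation the tomographic pipeline exists to remove, and the
main residual error source in the validation correlation below.

## Statistics

Spearman's rho is the Pearson correlation of mid-ranks (average ranks on
ties); the one-sample t-test is two-sided with n−1 degrees of freedom
(two-sided chosen as the stricter reading); summaries report mean ± SEM
(sample sd/√n).  A material is classified nanostructured when the mean
VSSA exceeds 60 m²/cm³ and the t-test rejects equality at α = 0.05.
Validation pairing is per-reconstruction totals: measured isosurface
area/volume vs ECD-calculated sphere-formula totals, across the fields of
a study.

## Study conditions and what the tests do (not) show

The default study is ten fields of one to eleven spheres (20 nm for the
classification study; 16–24 nm for the validation study) in 96³ voxel
volumes at 1 nm voxels — deliberately coarser than real acquisitions at
0.22–0.49 nm/px so a ten-field study runs in minutes on one CPU.  Field
seeds derive deterministically from the study seed.

Consequences of the scaled-down geometry, measured with the truth channel:

* The global threshold erodes blurred 20 nm particles, so measured volumes
  run ~0.6× truth and measured VSSA ~20–30% above the analytic 300 m²/cm³.
  Classification (≫60 m²/cm³) is unaffected.
* At radii of 4–5 downsampled voxels, reconstruction amplitude is
  particle-size dependent, so any single global threshold carries a
  size-dependent volume bias.
* Fields of 8–11 particles cannot pack without projected overlap in a 96³
  box; merged 2D regions inflate the ECD-volume total.  Together these
  hold the measured-vs-calculated Spearman correlations around 0.65–0.95
  per study, below the ≈0.98 a sparse, full-resolution acquisition
  achieves.  Passing tests therefore demonstrate pipeline correctness and
  classification power at desk scale, not the validation precision of a
  full-resolution instrument.

The generator also does not emulate diffraction contrast (a violation of
the projection requirement, excluded by design), focus effects/CTF, beam
damage, or support-film background.

## Numerical details

* Projector: bilinear footprints, float32 sparse CSR; rays sampled on the
  rotated grid, exact at 0°.
* Noise guard: Poisson counts clamped at 0.25 before the log.
* SIRT/ART normalisations guard zero rows/columns at 1e-8.
* Histogram ties break toward the lower grey value; labels are ordered by
  decreasing voxel count.
* MRC I/O is MRC2014 mode 2 (float32) with cell dimensions in Å; tilt
  metadata lives in a JSON sidecar, not the extended header.
* All lengths are nm internally; unit conversion only at I/O boundaries
  and in `compute_vssa`.
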