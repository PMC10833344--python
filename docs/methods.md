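# Methods

## Overview

`diffraqc` implements a simulation-to-model pipeline for per-image
diffraction quality control in macromolecular crystallography.  A
kinematic forward simulator produces diffraction images whose quality
parameters are known exactly, so every image is born labeled; a fixed
conditioning scheme turns frames of any detector into beam-anchored
512×512 arrays; and convolutional models regress per-image resolution
(through the B-factor↔resolution trend) or classify overlapping-lattice
("split crystal") diffraction.  Because the models consume only
conditioned pixels plus three geometry scalars, they have no tunable
parameters at inference time, which is what makes them suitable for
automated monitoring at high frame rates.

## Geometry

Flat single-panel detector at normal incidence, distance `D` (mm),
square pixels `p` (mm).  A pixel at radius `r` from the beam center
records scattering at `2θ = arctan(r/D)` and Bragg resolution
`d = λ / (2 sin θ)`.  Conversions are exposed as total, vectorized maps:
forward scattering (`r = 0`) returns a `+inf` sentinel rather than
raising, so per-pixel resolution maps need no special-casing.  The
inverse map raises once the scattering angle reaches 90°, the horizon of
a flat detector.  Both maps are mutual inverses to 1e-9 relative
tolerance and invariant under joint rescaling of `r` and `D`; the test
suite checks both properties.

Coordinates are 0-based `(slow, fast)` array indices; the beam center is
stored in raw-pixel units; radii are measured from pixel centers.
Detector tilt, parallax and multi-panel metrology are out of scope —
real multi-panel frames are expected to be flattened to one array by an
adapter before entering the pipeline.

## The B-factor ↔ resolution trend

Diffraction intensity decays with the overall Debye–Waller factor as
`exp(-B / 2d²)`.  Empirically, deposited structures show a smooth
relationship between achievable resolution `d` and overall `B`, modeled
here as a quadratic `B(d) = a d² + b d + c` that is fit on 1–4.5 Å and
flagged (not clamped) beyond 5.5 Å.  The shipped default
`(a, b, c) = (4, 0, 12)` is the classic rule-of-thumb `B ≈ 4 d² + 12`;
the coefficients are configuration, and `fit_trend` refits them from any
two-column `(d, mean B)` table, ignoring points outside the fit
interval.  We fit `B` as a function of `d` and invert analytically (the
unique positive root); the direction of the fit was an open design
choice and this one keeps inversion closed-form.

Monotonicity is enforced on the fit interval rather than down to
`d → 0⁺`: refits from noisy summary tables routinely carry a small
negative linear term that is harmless (and strictly monotone) on the
interval where the trend is ever evaluated.

## Simulator

The renderer is a self-contained kinematic model with the same
controllable knobs as the full physical simulators used for production
training (B factor, mosaic spread, lattice count, background, masks,
noise), deliberately simplified so that a labeled training image renders
in ~50 ms on one CPU core:

* **Lattice geometry.** Reciprocal-lattice points `q = U B h` are
  enumerated once per unit cell out to the corner resolution of the
  detector and cached; each scene only rotates and filters them.
* **Excitation.** Stills weight reflections by
  `exp(-ε²/2σ_E²)` where `ε` is the distance from the Ewald sphere and
  `σ_E = σ_floor + |q| (η + Δλ/λ)` collects a crystal-size floor
  (default 2×10⁻³ Å⁻¹), mosaic spread `η` and beam bandwidth
  (default 3×10⁻³).  Rotation frames accept at full weight any
  reflection whose `ε` changes sign across the rotation width — the
  simplest model of a reflection swept through the sphere, with no
  partiality profile.
* **Intensities.** `I = flux_scale · F² · exp(-B/2d²)` with `F²` drawn
  per reflection from the exponential (random-structure, "Wilson")
  intensity distribution.  Structure factors are not computed from
  atomic models: the learning targets depend on intensity statistics,
  not on any particular protein.
* **Spots.** Isotropic 2-D Gaussians (default σ = 1.2 raw pixels),
  normalized so a reflection's photons sum to `I`.
* **Background.** A radially symmetric profile in `q = 1/d`: a
  low-angle falloff plus a broad diffuse ring near 3.7 Å, scaled
  linearly by a background-scale knob sampled log-uniformly over
  0.01–1.25; optional sharp ice rings at 3.90/3.67/3.44 Å.  The exact
  experimental background shape is not part of the contract — only its
  symmetry, linearity and scale range are, and those are what the tests
  pin down.
* **Detector.** `counts = Poisson(expectation)·gain + N(0, σ_read)`,
  clipped to `[0, saturation]` and integer-cast; the beamstop disk is
  zeroed, bad-pixel rectangles get the `-1` sentinel, hot pixels
  saturate.

Sampled per scene (defaults in `SimulationConfig`): detector distance
uniform in 200–300 mm; wavelength fixed at 0.9795 Å; lattice count
1/2/3 with probabilities 0.50/0.25/0.25 (overlap task; the resolution
task always renders one lattice); misorientation spread drawn from
{0.1°, 1°, 10°} and applied as Gaussian-distributed rotations about the
nominal orientation; mosaic spread 0.005°; target resolution uniform in
1.5–4.5 Å, converted to `B` through the trend; beam-center jitter
Gaussian with σ = 3 raw pixels (the training distribution of beam-center
error is not specified anywhere authoritative, so this is an explicit,
configurable guess); beamstop radius uniform in 0.5–2 mm; up to 50 hot
pixels and 3 bad-pixel rectangles.  The default unit cell is a 50 Å
cube — small enough that the cached reciprocal grid keeps rendering
desk-scale, dense enough that images carry hundreds to thousands of
spots.  Whether production resolution training used stills or rotation
frames is not documented; the default here is stills with an optional
rotation width.

Determinism: `(config, seed)` fully determines every image byte.  Scenes
record their own noise seed, and `SimScene.to_json()` is byte-identical
across runs for the same seed.

## Conditioning

Fixed order: (1) group raw pixels into N×N blocks and keep the block
maximum (N = 2 or 4 per detector preset; block-max preserves sharp Bragg
peaks where mean-pooling would dilute them); (2) replace each value by
`floor(sqrt(value))` — an integer variance-stabilizing compression;
(3) cut four 512×512 quadrants anchored at the beam center, each flipped
so element (0,0) touches the beam center and scattering angle grows with
either index.  Identical conditioning is applied to simulated and
experimental frames.

Edge rules: partial edge blocks reduce over available pixels; the `-1`
mask sentinel participates as the minimum so an all-masked block stays
masked; padding past the detector edge is 0 (chosen over the sentinel to
avoid a third value class in training); quadrants larger than 512 are
truncated.  The quadrant order (UL, UR, LL, LR) is in array-memory
convention and the training quadrant is configurable (we train on UL by
default; which laboratory quadrant that corresponds to depends on the
detector's readout orientation).

## Models

Both models share one architecture: a convolutional backbone producing
1000 features, then FC1 (1000→100, bias), a rectified linear unit,
optional dropout, FC2 (100→1, bias), and a task head.

* Backbone depths 18/34/50 are the canonical residual networks with the
  first convolution reshaped to a single input channel.  The exact
  trainable-parameter counts are part of the contract:
  depth 50 → 25,550,760 backbone / 25,650,961 total (resolution);
  depth 34 → 21,791,400 / 21,891,601 (overlap); FC1 = 100,100 and
  FC2 = 101 always.  These counts uniquely pin down the two depths given
  the single-channel first convolution (the single-channel change
  removes exactly 64·7·7·2 = 6,272 weights from the canonical counts).
* The **geometry head** converts the scalar backbone output `s` —
  interpreted as an effective radial extent in downsampled-pixel units —
  to inverse resolution: `1/d = (2/λ) sin(½ arctan(s·p_eff/D))`.
  Regressing inverse resolution keeps the target finite and
  division-free; `s ≤ 0` maps to 0 Å⁻¹.  The head is differentiable,
  monotone in `s`, and exactly inverts the geometry-module conversions
  (tested to 1e-9).  Its precise functional form is this package's
  design; only self-consistency with the geometry module is claimed.
* The **overlap head** is a sigmoid on the scalar; binary cross-entropy
  against 0/1 (single/overlapping) labels; dropout after FC1 is enabled
  for this task (p = 0.5, off at inference).

The whole network stack (convolution via im2col + BLAS matmul, batch
normalization, pooling, dropout, SGD with momentum/weight decay) is
implemented natively on numpy with explicit backward passes, checked
against finite differences in the unit tests.  Deep backbones are built
and counted exactly; routine training in this package happens on the
"toy" depth: a fixed stem (crop/zero-pad to 256×256, 4×4 mean pool, so
any quadrant becomes a 64×64 field), three stride-2 conv+batch-norm
stages (12/24/32 channels), and a flatten→1000 projection.  The stem
crops to the leading 256×256 corner because that is the informative
region of a toy-detector quadrant; the toy depth is sized for the toy
preset by construction.

## Training

Stochastic gradient descent with momentum; seeded 90/10 train/test
split; per-epoch train/test loss and accuracy records; the checkpoint is
the weight snapshot at the best test accuracy (ties broken by loss).
Full-scale defaults: resolution — learning rate 6×10⁻³, momentum 0.9,
mean-absolute loss (the hyperparameter table is taken as authoritative
where the prose says mean-squared; both losses are implemented and a
flag switches); overlap — learning rate 1.04×10⁻³, momentum 0.9983,
weight decay 2.5×10⁻⁴, binary cross-entropy.  The regression accuracy
metric is the fraction of images within 0.07 Å⁻¹ of the ground truth.

Toy-scale runs use `toy_train_config`: the geometry head contracts
gradients by `d(1/d)/ds ≈ 3×10⁻³` per pixel unit, so the toy resolution
model trains at learning rate 0.5; the toy overlap model at 0.02;
batch 32, 30–40 epochs, optional per-epoch learning-rate decay.  FC2's
bias is initialized to 100 (a plausible mid-detector radius in
downsampled pixels) so the geometry head starts in its monotone regime.

Problem sizes used by the test suite: 2000 toy-detector images per task
(a 90/10 split), 30 epochs (resolution) / 40 epochs (overlap), and a
50-image memorization run — sizes chosen so the whole suite runs on one
CPU core at desk scale.  At these sizes the held-out resolution accuracy
reaches ≈0.88 and overlap accuracy ≈0.83 on the easy (10° spread) class
split.  These are property-based checks that the pipeline learns the
right quantities; they are not comparable to full-scale training runs
(hundreds of thousands of large-detector images), and nothing at toy
scale validates behavior on real detector data, pink beams, anisotropic
diffraction or ice/salt parasitic scattering.

## Inference and reporting

Each image yields one model pass per requested quadrant (1 for the
monitoring fast path, 4 for full coverage).  Resolution aggregates:
`d_min` (the best quadrant, i.e. largest inverse resolution) and
`d_mean` — averaged in inverse units, the model's native space, and then
inverted; a flag switches to averaging in d.  `B_min` is derived from
`d_min` through the trend rather than inferred separately.  Overlap
calls use `p ≥ 0.5` → overlapped (so `p < 0.5` defines the single
class); report rows carry per-quadrant values, aggregates and the call.
Dataset summaries are arithmetic means of per-image quantities
(`⟨B_min⟩`, `⟨d_min⟩`, overlapped fraction), and `sort_and_split`
stably sorts records by any key (overlap probability by default) into
near-equal groups, remainder to earlier groups — the operation used to
split an image set into cleaner/dirtier halves before merging.

## Known limitations

* Kinematic rendering only: no polarization fine structure, detector
  point spread, pink-beam spectra, absorption, or atomistic structure
  factors.
* The background profile is a documented stand-in with the correct
  symmetry/linearity, not a fit to any measured profile.
* Toy-scale training demonstrates learnability, not production accuracy;
  the deep backbones are exercised for construction and accounting, not
  trained here.
* Ice and salt diffraction are modeled only as optional background
  rings, not as parasitic lattices with their own class.
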