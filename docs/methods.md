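# Methods

This note documents the models and procedures implemented in
`actinpick`, the parameter defaults and why they were chosen, what the
synthetic data do and do not emulate, and the package's numerical
conventions.

## 1. The imaging model

### Volume library

The picker is trained to distinguish three per-pixel classes:
background, bare F-actin, and crosslinker-decorated F-actin. The
training data derive from a library of 3-D density volumes: one bare
filament and `n_models = 15` decorated variants that differ in the pose
of the crosslinker rod domain, emulating the conformational flexibility
of a filament-bound crosslinker. Default geometry is a 256-px cubic box
at 4.36 Å/voxel (the picking-scale pixel size, i.e. 1.09 Å × 4).

By default the volumes are parametric phantoms rather than experimental
maps, which keeps the pipeline free of external data while preserving
every downstream computation (the method is geometry-driven; any cubic
MRC volume can be substituted via `load_volume`):

* **Bare filament** — a parabolic-profile cylinder (radius 40 Å,
  roughly F-actin's) along the volume *z*-axis with a 30 %-amplitude
  helical surface modulation of period 55 Å (the long-pitch subunit
  repeat), extending past the box (length 1200 Å ≥ box diagonal side).
* **Decoration** — a compact spherical blob (radius 22 Å, an
  ABD/calponin-homology-domain-sized mass) centred 55 Å off-axis at the
  box mid-plane, marking the crosslinker–filament interface, plus a
  capsule-shaped rod arm (length 120 Å, radius 12 Å) attached to the
  blob. Across the library the rod direction sweeps a 120° fan in the
  plane perpendicular to the filament axis; the angular distribution of
  the real rod is unknown, so an even fan is used and is configurable.

Composition is purely additive, so decorated − bare density is
non-negative, and construction is deterministic. The canonical filament
axis is the volume *z*-axis: under the ZYZ rotation convention below,
tilt ≈ 90° then yields the side views that dominate real micrographs.

### Scene sampling

Each synthetic image contains 0, 1, 2, or 3 filaments with
probabilities (0.15, 0.6, 0.2, 0.05). Each filament is independently
bare with probability 0.5, otherwise one of the 15 decorated models
with probability 1/30 each. Poses: psi, rot ~ Uniform[0°, 359°];
tilt ~ Normal(90°, 10°), unclipped (out-of-range values are folded by
the rotation algebra); in-plane shift components independently
uniform in ±218 Å. A shift along the projection axis is invisible, so
translation is realized strictly in-plane.

Projection applies `R = Rz(rot) · Ry(tilt) · Rz(psi)` to the volume
(trilinear interpolation, zero fill), sums along *z*, shifts in-plane,
and centre-crops to the output box (128 px by default, so filaments
span the image). The uncropped identity-pose projection conserves total
density to 1e-6 relative.

### Corruption

The CTF is the standard weak-phase transfer function
`−[√(1−A²) sin γ + A cos γ]` with
`γ(k) = π λ Δz k² − (π/2) C_s λ³ k⁴`, relativistic λ at 300 kV,
C_s = 2.7 mm, amplitude contrast A = 0.07, and per-image defocus drawn
uniformly from 0.8–2.2 μm (the acquisition range; one draw per image).
Astigmatism, detector MTF, beam tilt, ice gradients, and motion blur
are not modelled.

Noise is synthesized in Fourier space with radial amplitude ∝ 1/f^α
(α = 1 by default; a measured radial amplitude profile can be
substituted) and random phases obtained by filtering white Gaussian
noise, which guarantees Hermitian symmetry and a real result. The
noise variance is set by `target_snr = var(signal)/var(noise) = 0.1`,
a typical cryo-EM value; the source data publish no SNR, so this is a
package convention recorded in every dataset manifest. The *reference*
signal variance is computed once per dataset from probe one-filament
projections, so noise power is a property of the imaging model rather
than of each scene's content — empty images are as noisy as crowded
ones, which is what a detector delivers. `add_pink_noise` alone (the
library function) defaults to the image's own variance and accepts an
explicit `reference_var`.

### Semantic targets

Each filament's noiseless projection is low-pass filtered at 30 Å
(sharp Fourier cutoff by default; Gaussian optional), binarized at 0.2
of its own maximum (a relative threshold is invariant to the arbitrary
density scale), and merged into a one-hot (background, bare, decorated)
map with decoration taking priority in overlaps. The whole decorated
filament is labelled decorated — the class describes filament identity,
and downstream 3-D classification is the stage that isolates
interface-bearing segments — but an interface-local labelling mode
(disc of 60 Å radius around the projected interface) is available.

## 2. Networks

Both networks are small fully convolutional encoder–decoders with skip
connections (stride-1 3×3 convolutions, 2×2 average pooling,
nearest-neighbour upsampling, channel-concatenation skips, 1×1 output
head), implemented directly in numpy with hand-written backpropagation
and Adam. Depth and width are constructor parameters; the defaults
(depth 3–4, base width 8) are sized for CPU training. The picking
pipeline is architecture-agnostic: anything with a
`predict_proba(tiles) -> (n, 3, H, W)` simplex plugs in.

* The **denoising autoencoder** regresses noiseless from noisy images
  under MSE in per-image-standardized intensity space; the validation
  metric is the mean per-image Pearson cross-correlation (images with
  constant targets — empty scenes — are excluded from the mean). It is
  a QC/visualization aid, not part of the default picking path.
* The **segmenter** is trained with class-weighted categorical
  cross-entropy. Background dominates the pixel count and, because a
  decorated filament carries a single localized decoration, most
  decorated-filament pixels are locally indistinguishable from bare
  ones, which makes the decorated class both rare and partially
  ambiguous. Training therefore weights it up (inverse-frequency
  "balanced" weights by default; explicit weights configurable). The
  picking objective is recall-oriented — false positives are removed
  downstream by classification, missed interfaces are gone forever —
  so a decorated-favouring weighting is the intended operating point.
  With weights (w_bg, w_bare, w_dec), a filament pixel whose local
  evidence cannot distinguish decoration converges to a decorated
  posterior of w_dec/(w_dec + w_bare); choosing odds well above the
  0.8 binarization threshold (e.g. 1:2:30, posterior ≈ 0.94) makes
  decorated-filament recall insensitive to calibration wobble during
  training, at the documented cost of picks on bare filaments. An
  optional exponential moving average of the weights (`ema_decay`)
  smooths the SGD trajectory; the averaged weights become the fitted
  model. Reported validation cross-entropy is always *unweighted*.

Inputs are standardized per image (zero mean, unit variance) inside the
estimators, and the identical transform is applied to micrograph tiles
at inference. Training is deterministic given the seed (pure numpy);
the train/validation split is a seeded random 90/10.

## 3. Coordinate extraction

Micrographs are Fourier-crop downsampled (exact amplitude preservation
below the new Nyquist; ×4 by default, 1.09 → 4.36 Å/px), tiled into
128-px boxes advancing by 96 px (32 px overlap) with edge tiles clamped
to the boundary (no fabricated pixels), segmented per tile, and
stitched by per-channel per-pixel maximum. Because a per-channel max
breaks the sum-to-one property, channels are renormalized after
stitching so the binarization threshold stays on a probability scale.
The decorated channel is thresholded at 0.8, skeletonized
(topology-preserving thinning to 1-px width), and skeleton pixels are
reduced by greedy non-maximum suppression: candidates are visited in
descending stitched-probability order (ties broken row-major for
determinism) and each accepted pick suppresses all candidates within
44 Å — enforced in physical units via the downsampled pixel size
(10.09 px at 4.36 Å/px), not a rounded pixel count. Coordinates are
exported 0-based, x = column, in full-resolution pixels, as STAR files
(`rlnCoordinateX/Y`, `rlnAutopickFigureOfMerit` = stitched probability)
with shortest-round-trip number formatting so coordinates re-read
exactly.

The spacing bound is a hard invariant of every emitted pick list, and
every suppressed candidate is within 44 Å of an accepted pick of
greater-or-equal score.

## 4. Scaled-down study sizes

The full-scale protocol (200,000 denoiser pairs, 10,000 segmenter
pairs, 128-px images, converged GPU-scale networks) is the package's
default *configuration*, but the shipped tests exercise the pipeline at
sizes chosen for a single CPU:

* distribution checks: 10,000 scenes / 100,000 poses;
* oracle checks: 64–96-px volumes, 512-px noise fields;
* truth-path recall: 50 stratified scenes on 64-px boxes;
* learning check: 1,500 paired 64-px images, a depth-4/width-8
  segmenter trained 14 epochs (batch 16, Adam 2e-3, class weights
  1:2:30, weight EMA with decay 0.99), then picking on twenty 128-px
  held-out synthetic micrographs with 64-px tiles (matching the
  training receptive scale) and 32-px overlap.

A decorated filament counts as recovered if any pick falls within its
truth decorated mask dilated by 3 px (≈13 Å); this tolerance, like the
≥80 % recall bar it feeds, is an artifact-level check of the scaled-down
pipeline, not a reproduction of the source study's converged metrics.

## 5. What the synthetic data do not show

Passing these tests demonstrates internal consistency of the simulator,
the trainability of the networks on the simulator's own distribution,
and the correctness of the deterministic extraction geometry. It does
not demonstrate performance on real micrographs: phantoms lack true
helical density detail, structured backgrounds (carbon edges, ice
contamination, aggregates), astigmatic/local CTF variation, radiation
damage, and crowded overlapping fields beyond three filaments; the
parametric pink noise lacks the structured spectra of real detectors.
Real deployments should substitute experimental maps for the phantoms,
measure an empirical noise profile, and train at the full-scale sizes.

## 6. Numerical conventions and degenerate inputs

* Volumes are float32; rotation uses trilinear interpolation with zero
  fill; identity rotations bypass interpolation.
* `tilt_sd = 0` / `t_max = 0` produce exact degenerate poses.
* Zero-density volumes project to exactly zero; empty scenes produce
  all-background targets and (dataset path) pure-noise images.
* An all-background segmentation yields a valid empty pick list, and
  empty pick lists export valid STAR files with empty loops.
* A probability channel exactly at threshold is included (`>=`).
* Fourier-crop downsampling trims dimensions to a multiple of the
  factor before cropping; DC is preserved exactly.
* Library weights are stored as `.npz` with a JSON sidecar recording
  architecture, seed, and normalization convention.
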