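# actinpick

Neural-network particle picking for crosslinker-decorated actin filaments
in cryo-EM micrographs, trained entirely on synthetic data.

## The problem

Structural studies of actin crosslinkers (α-actinin-4 and relatives) need
hundreds of thousands of particle images centred on the sparse, faint
crosslinker–F-actin interfaces scattered along filaments in cryo-EM
micrographs. Template pickers select filament segments indiscriminately;
manual picking does not scale. This package implements the alternative:
simulate micrograph-like images with perfect ground truth, train a
semantic segmentation network to distinguish *background*, *bare
F-actin*, and *crosslinker-bound F-actin* per pixel, and reduce the
network's decorated-channel output to particle coordinates with
deterministic morphological post-processing.

It is aimed at cryo-EM practitioners who want a picker for
decorated-filament specimens without hand labelling, and at method
developers who want a fully seeded, self-contained reference pipeline.

## What it does

**Simulation.** A library of 3-D density volumes — one bare F-actin
phantom plus 15 decorated variants with the crosslinker rod arm in
different poses (256-px boxes, 4.36 Å/voxel by default; experimental MRC
maps can be substituted) — is projected into 2-D scenes. Each image
contains 0–3 filaments with probabilities (0.15, 0.6, 0.2, 0.05); each
filament is bare with probability 0.5 or one of the 15 decorated models
at 1/30 each. Poses use ZYZ Euler angles with psi, rot ~ U[0°, 359°],
tilt ~ N(90°, 10°), and in-plane shifts within ±218 Å. Projections are
corrupted by a contrast transfer function,

    CTF(k) = −[√(1−A²)·sin γ(k) + A·cos γ(k)],
    γ(k) = π λ Δz k² − (π/2) C_s λ³ k⁴,

(300 kV, C_s 2.7 mm, A = 0.07, defocus drawn from 0.8–2.2 μm), then by
pink noise synthesized in Fourier space with amplitude ∝ 1/f^α. Ground
truth is a one-hot 3-channel map built by 30 Å low-pass filtering and
binarizing each filament's noiseless projection.

**Training.** Two numpy convolutional encoder–decoders with
scikit-learn-style interfaces: a denoising autoencoder
(`DenoisingAutoencoder`, MSE loss, validated by per-image Pearson
cross-correlation) and a 3-class segmenter (`SemanticSegmenter`,
categorical cross-entropy). Any model mapping image tiles to per-pixel
3-channel probabilities plugs into the picker.

**Picking.** Micrographs (1.09 Å/px) are Fourier-crop downsampled ×4,
cut into 128-px tiles with 32 px overlap, segmented, stitched by
per-channel maximum-intensity projection, renormalized; the decorated
channel is binarized at 0.8, skeletonized, and reduced by greedy
non-maximum suppression to coordinates at least 44 Å apart, exported as
RELION-style STAR files.

## Worked example

```python
import numpy as np
from actinpick import (PhantomParams, PoseParams, build_model_library,
                       generate_dataset, SemanticSegmenter, PickerParams,
                       Micrograph, pick_micrograph)

library = build_model_library(PhantomParams(), n_models=15,
                              box_px=64, voxel_size=4.36)
ds = generate_dataset(n=600, seed=11, library=library,
                      pose_params=PoseParams(t_max=60), box_px_out=64)
print(ds.noisy.shape, ds.targets.shape)

seg = SemanticSegmenter(depth=4, width=8, epochs=12, batch_size=16,
                        learning_rate=2e-3, seed=0)
seg.fit(ds.noisy, ds.targets)
print(f"validation cross-entropy: {seg.val_metric_:.3f} "
      f"(uniform baseline ln 3 = {np.log(3):.3f})")
```

prints

```
(600, 64, 64) (600, 3, 64, 64)
validation cross-entropy: 0.689 (uniform baseline ln 3 = 1.099)
```

— 600 paired 64-px images with one-hot targets, and a small segmenter
whose held-out cross-entropy (0.689) is well below the
uniform-prediction baseline (1.099): the network has learned to separate
filament from background and to flag decorated regions. Picking then
takes one call per micrograph:

```python
m = Micrograph(image, pixel_size=1.09, path="mic_0001.mrc")
picks = pick_micrograph(m, seg, PickerParams())
# picks.coords are full-resolution (x, y) pixels;
# picks.min_pairwise_spacing_A() is guaranteed >= 44
```

The command-line interface mirrors the library:
`actinpick simulate`, `actinpick train-segmenter`, `actinpick pick
--micrographs '*.mrc' --weights seg.npz --out picks/`.

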