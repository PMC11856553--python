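# Methods

## The procedure

`xaiseg` treats a trained 2-class image classifier as the encoder of a
segmentation network and an attribution method as its surrogate decoder.
The pipeline is:

1. **Data.** 2D grayscale slices, either synthesised phantoms or axial
   cuts of a NIfTI volume (per-volume min-max scaled to 8 bit, filenames
   `<id>_slice_<k>_modality_<m>.png`).
2. **Classifier.** A convolutional backbone whose final layer is replaced
   by a 2-way head (tumour / no tumour); nothing else changes.
3. **Attribution.** A heatmap for the *tumour class* (class 1, not the
   predicted class — the object of interest is fixed), min-max normalised
   to [0, 1] on absolute attributions.
4. **Postprocessing.** Threshold at 0.35 → component filtering →
   hole-fill + elliptical closing → convex hull of the thresholded
   foreground → filled binary mask.
5. **Evaluation.** Dice and IoU against ground truth, with the identity
   J = D/(2−D) checked on every pair.

## The classifier

The backbone is a pure-NumPy convolutional network: 3×3 stride-1
convolutions, ReLU, 2×2 max pooling between stages, global average
pooling, linear head. Running in float64 with hand-written backward
passes gives machine-precision input gradients (finite-difference
agreement ~1e-11), named access to every stage's activations and
gradients, and a togglable guided rectifier rule — the exact contract the
attribution layer needs. Two variants are bundled:

- `make_test_backbone()` — 4 stages, widths (8, 16, 32, 32); the
  contract- and oracle-testing network, trains in seconds.
- `make_segmentation_backbone()` — 5 stages, widths (8, 16, 32, 64, 64);
  the network used for end-to-end segmentation. Guided backpropagation's
  noise suppression compounds with the number of rectifier gates along
  the backward path, so the fifth stage markedly reduces stray
  suprathreshold pixels — which matters because the convex-hull step
  amplifies any outlier into a large mask error.

Max pooling (not average) is used deliberately: average pooling smears
gradient uniformly over each window, while max routing — combined with
rectifier gating — is what gives guided backpropagation its
characteristically sharp input maps.

**Training protocol** (`TrainConfig` defaults): Adam, learning rate 1e-3
with a 10× step decay after 75% of 40 epochs, batch 16, 80/20
train/validation split, weight decay 1e-4, and a logit-sum penalty
0.5·λ·(y₀+y₁)² with λ = 0.1. The last two serve the *attribution*, not
the accuracy (validation accuracy reaches 1.0 on phantoms regardless):
weight decay shrinks weights carrying no discriminative signal, and the
logit penalty pushes the two logits antisymmetric so that ∂y₁/∂x
approaches the purely discriminative direction ½·∂(y₁−y₀)/∂x. Both
concentrate the tumour-class gradient on class evidence.

The default input size is 64×64 (bilinear resize from the phantom's
native 240×240); the whole stack is input-size agnostic thanks to the
global-average-pool head, and 64×64 keeps a full train-attribute-evaluate
cycle around half a minute on one CPU. Masks are produced at the network
resolution and upsampled to the source resolution by nearest neighbour
before scoring, mirroring the mask-resize step of the overlay stage.

## The phantom generator

Each phantom emulates one axial brain slice as the method assumes it:

- **head**: a filled ellipse (semi-axes 70–100 px at 240×240, random
  orientation, ±4 px centre jitter) at base intensity 0.40 with smooth
  low-frequency texture of amplitude 0.10 (coarse 8×8 Gaussian grid,
  bilinearly upsampled), on a 0.02 background;
- **tumour** (class 1 only): a perturbed ellipse of mean radius 15–30 px
  — axes r·s and r/s with s ∈ [1, 1.15] preserve area ≈ πr², plus a
  zero-mean radial perturbation (orders 2–4, amplitude ≤ 0.12) so the
  blob is not exactly convex and the hull step does visible work. It is
  placed fully inside the head and adds 0.5 intensity;
- additive Gaussian noise (σ = 0.02), final clip to [0, 1].

The contrast construction guarantees separability: mean tumour intensity
exceeds the surrounding head annulus by ≥ 0.25 (half the added contrast)
under the default texture and noise, so the classification task is
learnable by design. What the phantoms deliberately do **not** model:
MRI physics (bias fields, partial-volume effects, coil profiles),
multi-modal acquisition, infiltrative or multi-focal lesions, and
low-contrast tumours. Passing the end-to-end suite therefore shows the
*mechanism* works — image-level supervision suffices to localise a
well-defined high-contrast object — not that any particular Dice carries
over to clinical data, where object boundaries blur and classifiers
exploit context.

## Postprocessing fidelity

The mask pipeline follows the published procedure exactly in its default
`faithful` mode, including two quirks that are reproduced rather than
repaired:

- the neighbour-count condition before component dilation
  (`sum(neighbours) > cluster_size`) is mathematically always true for a
  non-empty component — the convolution sum equals kernel-area × size —
  and is kept as printed;
- the hole-filled/closed intermediate is computed but *not* used: the
  final convex hull is taken over the raw thresholded foreground.

`mode="cleaned"` instead hulls the filled-and-closed mask; on multi-blob
heatmaps the two modes differ (cleaned hulls the dilated foreground and
is a strict superset). Numerical conventions: threshold is inclusive
(value = 0.35 maps to background); component labelling uses
4-connectivity by default (8 via config); the elliptical closing element
follows the standard filled-ellipse construction (for size 5: full rows
in the middle three, centre pixel in the outer rows); hulls need ≥ 3
non-collinear foreground pixels, otherwise the mask is empty; hull
vertices are (row, col) pixel coordinates flipped to (x, y) for polygon
rasterisation, with boundary pixels included. Grayscale conversion uses
luminance weights (0.2125, 0.7154, 0.0721) so the absolute threshold is
reproducible.

## Attribution conventions

- Multi-channel attributions reduce by the **maximum of absolute
  values** across channels — preserves thin high-attribution structures
  that a mean would dilute.
- Normalisation is per-heatmap min-max on absolute attributions; an
  all-equal raw map (e.g. from a constant scorer) normalises to all
  zeros rather than all ones.
- Rectifier ties: "positive" means strictly positive; a pre-activation
  of exactly 0 blocks gradient in guided mode.
- Occlusion defaults: 16×16 window, stride 8, baseline 0.0 — covers a
  240×240 input in under 1000 forward passes. Pixels covered by no
  window placement attribute zero.
- Grad-CAM defaults to the last convolutional stage, upsampled
  bilinearly; its map is non-negative by construction (rectified sum).
- Layer attributions keep their native (K, h, w) resolution; channel
  selection is explicit, reflecting that layer/neuron methods require a
  manual choice of channel.

## Problem sizes

The shipped study conditions: 200 phantoms at 240×240 (half with
tumour), classifier input 64×64, 40 epochs, 20 held-out tumour slices
for evaluation. One full acceptance run — training included — takes
roughly 40 s on a single CPU; the complete test suite runs in about two
minutes. Gradient oracles use 16×16 inputs on the 4-stage backbone,
perturbation oracles 32×32.

## Known limitations

- The faithful-mode mask is always convex, so non-convex lesions are
  over-segmented by construction; the Dice ceiling on strongly concave
  shapes is < 1 even with a perfect heatmap.
- The convex hull is extremely sensitive to stray suprathreshold
  pixels; the method's accuracy is therefore tied to how clean the
  attribution map is (depth of the backbone, training protocol), not
  only to whether the classifier is accurate.
- Layer and neuron methods require manual channel/unit selection and are
  exposed as building blocks, not as an automated segmentation route.
- Timing tables (`benchmark_methods`, `xaiseg benchmark`) are
  hardware-dependent and reported only, never asserted.
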