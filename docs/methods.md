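# Methods

## Problem setting

Macroscopic wood identification is texture classification: on the
transverse surface, the diagnostic characters are the size, density and
arrangement of pores (vessels), the spacing of rays, and the presence of
parenchyma bands and growth-ring boundaries. Wood anatomy is typically
diagnostic at the genus rather than species level, so the pipeline
evaluates both granularities and the mapping between them ("clubbing":
counting a wrong-species/right-genus prediction as correct).

## Synthetic texture model

Real reference photographs of the 10-species Meliaceae collection are not
publicly available, so `xylotype.synthetic` renders the anatomy
procedurally. One image is composed additively on a grey field:

- background tone plus low-frequency mottle and per-pixel grain
  (`tone_jitter_sd`, 8-bit units);
- growth rings: a sinusoidal tonal gradient of period
  `ring_boundary_period` (px) along the radial (row) axis, amplitude 7;
- parenchyma: light Gaussian-profile bands of period
  `parenchyma_band_period`, lift 16;
- rays: dark vertical lines of width `ray_width` at normally-jittered
  spacing (`ray_spacing_mean/sd`), depth 14;
- pores: dark near-circular ellipses; their count is Poisson with mean
  `pore_density` (pores/mm²) times the 6.35 mm × 6.35 mm field of view;
  `diffuse` positions are uniform, `ring-banded` positions cluster in rows
  of the ring period; radii are normal (`pore_radius_mean/sd`, px), depth 55.

Exposure is emulated by shifting the field so its mean equals the target
intensity (default 128, matching a capture protocol that centres the
histogram there); rendered means stay within ±10 of the target. RGB is a
warm tint pivoted at the target mean (R lifted, B lowered by 25 % of the
distance from the pivot), so a flat mid-grey field stays neutral and the
channel-averaged intensity is preserved while downstream code receives the
3-channel input the backbone expects.

**Class structure.** Each species has base parameters; each *specimen*
draws its own parameters from a normal law per field with sd
`rel_sd × base × intra_class_sd_scale` (rel_sd 4–10 % per field), and each
image of a specimen re-renders with fresh noise. The 10-species preset
encodes the field's expected confusion structure: genera carry distinct
macro-signatures; the two *Cedrela*-like species are byte-identical twins
(pronounced ring-banded pore rows make the genus highly distinct while the
species stay inseparable); the *Cabralea*- and *Guarea*-like classes are
mutually similar; the *Carapa*-like class has `intra_class_sd_scale` 2.5,
making it the most internally variable. Image counts per class follow the
reference collection's imbalance (total 2303 at scale 1; `scale` rescales).

**What the generator does not emulate:** surface-preparation artifacts,
lens distortion and lighting gradients, non-stationary anatomy (knots,
reaction wood), and inter-image correlation beyond shared specimen
parameters. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that its accuracy orderings follow from the
encoded class structure — not that the model reaches any particular
accuracy on photographs.

## Dataset construction

Splitting is stratified per species; `train_fraction` accepts a per-class
mapping so the preset reproduces the reference collection's per-class
train/test counts exactly (its global split is ≈69/31). The split unit can
be the image (reference protocol) or the specimen; the latter guards
against specimen leakage. A single-image stratum goes to train with a
warning.

Patches are full-height vertical strips; training/testing patches are
placed at uniform-random horizontal offsets, assigned round-robin over a
class's images (per-image counts differ by ≤1), with overlap permitted
whenever the quota exceeds the disjoint positions — the minority-class
oversampling mechanism. Offset RNGs are seeded from (seed, level, class,
split, image basename), so manifests are independent of where the image
directory lives. Image-level evaluation instead uses 5 equally spaced
offsets `round(i·(W−w)/(n−1))`; n=1 centres the patch. The genus dataset
samples the species manifest per genus/split proportionally to species
image counts with largest-remainder rounding (ties to the lower index).

## Classifier and training

The NumPy layer stack exists because the pipeline needs full
backpropagation through convolutions and no deep-learning framework is a
dependency of this package; convolutions are evaluated as im2col matrix
products, and the gradient of every layer is verified against central
finite differences in the test suite.

Numerical choices worth knowing:

- **Initialization.** He-normal for convolutions, Glorot-uniform for the
  dense layer, from a single seeded generator; assembly is reproducible.
- **Batch normalization** sits between global pooling and dropout and
  normalizes the pooled energy vector. With batch size 8 the exponential
  running statistics are noisy and lag the fine-tuned weights, which
  distorts evaluation-mode predictions; the trainer therefore recomputes
  the BN input's exact population mean/variance over the training patches
  (under current weights) before every monitored evaluation and at phase
  end. During the frozen phase the BN input distribution is constant, so
  one calibration suffices.
- **Optimizers.** Phase 1: SGD with momentum on the head only; the frozen
  backbone's feature maps are computed once and cached, making phase-1
  epochs nearly free. Phase 2: Adam; "decay" is per-step learning-rate
  decay lr/(1+decay·t) by default (the semantics of the era's framework),
  with decoupled weight decay available via `decay_mode="weight"`.
- **Early stopping** monitors a patch set's accuracy; improvement is
  strict (ties do not count), the run stops when `epoch − best ≥ patience`,
  and the best epoch's weights (including BN statistics) are restored. By
  default the monitor is a stratified validation split carved from the
  training patches (`val_fraction`); monitoring the test split — which
  leaks test information into model selection but reproduces the reference
  protocol — is available via `monitor: test`.
- **Ties** in any argmax (patch prediction, summed image scores) resolve
  to the lowest class index.
- **Degenerate inputs.** A zero-epoch phase is a strict no-op; an empty
  patch set, a class absent from training labels, or a non-finite loss
  abort with explicit errors.

`pretrained` accepts a path to an `.npz` backbone checkpoint and loads it
before training; no checkpoint ships with the package, and `pretrained=True`
without a path is rejected with an explanatory error. All presets train
from seeded random initialization.

## Desk-scale study conditions

The default `RunConfig` is the desk-scale experiment: 10-species preset at
scale 0.1 (229 images of 256×256 px), 256×96 strips resized to 64×24,
quotas 64/24 per class, `mini` backbone, phase 1 of 30 epochs at lr 10⁻²
(the reference 10⁻⁴ presumes a pretrained backbone and does not move a
randomly initialized head), phase 2 of up to 50 Adam epochs with patience
10, validation fraction 0.25. These sizes keep a full species+genus run
around a minute on one CPU while leaving the accuracy structure intact;
the full-scale geometry (2048 px images, 2048×768→1024×384 patches,
500/200 quotas, truncated VGG16) remains the library default for
`PatchSpec`, the CLI and the structural checks.

Expected behaviour under these conditions (asserted over 3 seeds in the
acceptance tests): explicit-genus ≥ clubbed-genus ≥ species image accuracy
on seed-averages, species patch accuracy ≥3× the 10-class chance level,
and ≥80 % of the twin species' misclassified images staying within their
genus.

## Known limitations

- The NumPy stack is single-device and unsuited to the full 2048-px
  geometry at training time; the truncated VGG16 assembles and runs but is
  practical only for inference-scale experiments here.
- Byte-identical reproducibility holds for a fixed BLAS configuration
  (thread count); differing threading may reorder floating-point
  reductions.
- The synthetic preset's parameter distances are a qualitative encoding of
  the expected confusion structure; no quantitative anatomical
  measurements stand behind them.
- Confusion-matrix rows without test support are reported as NaN and
  flagged, never renormalized.
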