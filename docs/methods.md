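# Methods

This note documents the models and procedures implemented in `histotex`,
the defaults they ship with, and the design decisions taken where the
underlying method leaves choices open.

## Texture matrices

**Quantization.** Images are converted to grayscale with Rec. 601 luminance
weights (0.299, 0.587, 0.114) and binned into `G` equal-width levels via
`level = floor(v · G / 256)`, so 255 maps to the top bin and `G = 256` is
the identity on grayscale input.  The luminance is rounded to 6 decimals
before binning because the weights sum to 1 − ε in floating point, which
would otherwise drop exact integer values one bin low.  Default `G = 8`.

**GLCM.** Pair counting is *directed* (asymmetric): `counts[i, j]` counts
pixels at level `i` whose neighbor at offset `(d, θ)` has level `j`, with
offsets `(0,+d)`, `(−d,+d)`, `(−d,0)`, `(−d,−d)` for θ = 0°, 45°, 90°, 135°
(row axis pointing down; 90° looks up the image).  Neighbors outside the
grid are skipped; a distance leaving zero valid pairs is an explicit error
rather than an empty matrix.  Normalization divides by the total number of
valid pairs so the normalized matrix is a probability distribution (sums to
1), which is the testable reading of "normalize by the total number of
components".  Symmetric accumulation (`counts + countsᵀ`) is available as a
flag.  Note scikit-image's `graycomatrix` measures angles in image
coordinates, so its 45°/90°/135° matrices are the transposes of ours — the
test suite uses it as an independent oracle through that mapping.

**GLRM.** For each orientation the grid is partitioned into scan lines
(rows, columns, anti-diagonals, diagonals); every maximal run of `n` equal
levels at level `m` increments `Q[m][n]`.  Because the lines partition the
grid, `Σ n·Q[m][n] = N·M` holds for every orientation — a conservation law
the tests enforce.  `L = max(N, M)` columns are always allocated (trailing
zero columns retained) so the matrix shape is independent of the realized
maximum run length.

## Textural images

The four per-orientation matrices must become one RGB image for a CNN.  The
method itself does not pin down this rendering, so three deterministic
modes are provided:

* `matrix` (default): element-wise mean of the four normalized matrices →
  min-max scale to [0, 1] → fixed perceptual colormap (viridis) →
  nearest-neighbor upsample to the backbone input size.  Chosen as default
  because it preserves the full gray-level structure in a single image.
* `tiled`: the four orientations rendered separately in a 2×2 grid.
* `local`: a sliding-window map (window 32, stride 16) of a per-orientation
  summary statistic — GLCM contrast or GLRM short-run emphasis — averaged
  over orientations; spatially resolved but discards level structure.

A degenerate (constant) matrix renders uniform mid-colormap, never NaNs.
Rendering is bit-deterministic for identical inputs.

## Synthetic data generator

The generator emulates a four-class labeled histology-texture dataset; its
default class distribution is 59/42/30/23 (the 154-image study
distribution).  Classes are distinct stationary texture processes layered
on a shared correlated-noise baseline: long-correlation Gaussian random
field (classic), oriented sinusoidal stripes (desmoplastic), Poisson-placed
dark blobs (large_cell), and fine speckle (nodular).  Grayscale amplitudes
are mapped through a fixed affine into [0, 1] and tinted with a two-tone
H&E-like colormap (dark purple → light pink).

`separability ∈ [0, 1]` interpolates every class toward the shared baseline:
at 0 the labels carry no texture information (a linear classifier on GLCM
summaries sits at chance), at 1 the processes are maximally distinct (the
same classifier exceeds 98% held-out accuracy at 40 images/class).  Each
image uses a private PRNG substream derived from `(dataset seed, counter)`,
so outputs are bit-identical across runs and independent of generation
order.

What the generator does *not* emulate: nuclei, stain physics, microscope
optics, JPEG artifacts, inter-center staining variability.  Passing tests
on synthetic data therefore demonstrate the pipeline's mechanics and the
fusion effect under controlled separability — not clinical performance on
real photomicrographs.

## Preprocessing

Resizing is bilinear to the backbone's input size, aspect ratio not
preserved.  The Inception-family input default is kept at 229×229×3 as
printed in the study settings even though standard releases of those
architectures use 299×299; the value is configurable, not silently
corrected.  Augmentation draws per-copy affine transforms — translation
(−30, 30) px, scale (0.9, 1.1), optional x/y flips, shear (0, 45)° in x and
y — from a stream keyed by `(seed, image_id, draw_index)`.  Warps use
bilinear interpolation with reflect borders (black borders would corrupt
texture statistics).  Augmentation is applied only to backbone-training
partitions; classifier cross-validation always operates on unaugmented
images, and augmented copies carry a `parent_id` that group-aware CV uses
to prevent leakage.

## Backbones and deep features

A deep feature vector is the *pre-softmax* activation of the final fully
connected layer — length equal to the number of classes (4) — extracted in
evaluation mode; post-softmax output is a config switch.  Training uses
minibatch SGD with momentum 0.9, constant learning rate 3·10⁻⁴, mini-batch
4, 200 epochs, with loss/held-out accuracy logged every 26 iterations
(defaults mirroring the study settings; all configurable).

The bundled `tiny_cnn` backbone is a desk-scale network: a fixed, seeded
three-block convolutional pyramid (3×3 conv → ReLU → 2×2 average pool;
8/16/32 channels) pools into a 160-dim descriptor, and only the fully
connected head (hidden 32 → 4) is trained, via scikit-learn's MLP driven by
an explicit minibatch loop.  `pretrained=True` selects a canonical filter
bank shared by all runs (transfer-style reuse of fixed weights);
`pretrained=False` draws filters from the user seed.  The ImageNet
architectures (ResNet-101, Inception) are available behind the optional
torch extra with their final layer replaced and all layers fine-tuned;
without that extra the registry raises a clear error for them.  The package
makes no claim that tiny_cnn approximates those architectures — it exists
so the full pipeline is exercisable and reproducible on one CPU.

Feature standardization for the head uses training-set mean/std of the
conv descriptor.  Extraction never mutates weights (enforced by checksum in
tests) and an untrained handle extracts through a deterministic seeded
random head with a warning, rather than failing.

## Fusion

Plain concatenation with no rescaling, within a single backbone: GLCM then
GLRM (length 8), then spatial first for the full descriptor (length 12).
Keeping fusion pure makes the length contracts exact; standardization, when
needed, is a classifier-side concern.  Feature tables are keyed by sorted
`image_id` with provenance-named columns, so assembly is invariant to input
order, and a missing component vector is an error naming the image.

## Classifier bank and evaluation protocol

Six classifiers with standard defaults, all config-exposed: LDA (SVD
solver), QDA, SVM with quadratic polynomial kernel (one-vs-one), Gaussian
naive Bayes, k-NN (k = 5, Euclidean), random forest (100 trees, √d feature
subsampling, seeded).  SVM and k-NN get fold-local standardization; the
covariance/tree-based kinds see raw features.  When a discriminant fit hits
a singular class covariance (common with more features than per-class
samples), the fit falls back to a ridge-regularized solver — LDA: `lsqr`
with shrinkage 10⁻³; QDA: eigen solver with shrinkage 10⁻³ and a tiny rank
tolerance — with a logged warning.

The evaluation protocol is stratified, group-aware 5-fold cross-validation
with a fixed seed: every sample is predicted exactly once by a model that
saw neither it nor any augmented copy of it.  A class with fewer samples
than folds is an explicit error suggesting a smaller k.

Metrics are computed from one-vs-rest confusion counts per class:
accuracy, sensitivity, specificity, precision, F1 and MCC, with 0/0 ratios
defined as 0 plus a structured warning.  Multiclass summaries are
macro-averaged (unweighted over the four classes) — declared, logged, and
chosen because the binary formulas require an averaging rule for a 4-class
problem — alongside the overall accuracy trace(confusion)/n.  ROC curves
come from a threshold sweep over unique scores with midpoint tie handling;
the trapezoidal AUC then equals the normalized Mann–Whitney U statistic,
which the tests verify to 1e-12.

## Pipeline, determinism and problem sizes

The orchestration runs preprocessing → textural-image generation →
per-backbone training on the three image kinds → feature extraction →
two-step fusion → the classifier grid → reports.  Each checkpointed stage
records a hash of its resolved inputs; re-running with unchanged inputs is
a no-op, and the run directory (resolved config, package version, seed) is
sufficient for third-party reproduction.  All randomness derives from the
single global seed via fixed offsets.  Two identically seeded runs produce
byte-identical report JSON.

Shipped problem sizes: the smoke profile uses 8 synthetic images per class
at 64×64 with 30 head-training epochs and 4-fold CV; the synthetic fusion
benchmark uses 40 images per class, 60 epochs and 5-fold CV; the
acceptance script uses the full 59/42/30/23 distribution at 256×256 with
the default 200 epochs.  These sizes were chosen so a complete run is a
matter of seconds to about a minute on a single CPU while keeping all four
classes well represented.

## Known limitations

* The printed 100%-type accuracies on maximally separable synthetic data
  say nothing about real histopathology; the synthetic benchmark is a
  mechanism check, not a clinical validation.
* tiny_cnn trains only its fully connected head; full fine-tuning requires
  the optional torch backbones.
* At high per-class accuracy the fusion comparison saturates — on easy
  synthetic data most feature sets reach near-perfect accuracy, so the
  fused-vs-component comparison is a floor (`fused ≥ worse component`)
  rather than a strict improvement.
* GLRM rendering treats the run-length matrix like a distribution over
  (level, length); very elongated `L` (large images) makes the heatmap wide
  and sparse before resizing.
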