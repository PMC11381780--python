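# Methods

## Problem setting

Three endometrial conditions — non-atypical hyperplasia (NAEH), atypical
hyperplasia (AEH) and endometrial cancer (EC) — are hard to separate on
transvaginal ultrasound, and labeled images are scarce. The pipeline
treats the task as 3-way K-shot metric classification: a support set of
K labeled images per class defines the classes; every query image is
assigned the majority label among its k nearest support images in a
feature space, under the Euclidean metric. No episodic meta-training is
performed; the feature space comes either from handcrafted texture
descriptors or from a transfer-trained CNN truncated at its 64-unit
layer.

## Synthetic phantoms

Real images are private, so the package generates seeded surrogate
cohorts. Each phantom is a 256×256 grayscale field

    image = clip( (base + grating + blobs) × speckle, 0, 1 )

with one elliptical lesion mask per image (area 5–40 % of the frame,
seeded center/axes/orientation). Speckle is multiplicative unit-mean
gamma noise — the standard surrogate for the granular noise of coherent
imaging; the gamma shape sets graininess (variance 1/shape). Three
presets define the default classes:

| preset        | base | speckle shape | grating          | blobs          |
|---------------|------|---------------|------------------|----------------|
| homogeneous   | 0.55 | 12 (smooth)   | —                | —              |
| directional   | 0.50 | 4             | amp 0.18 at 30°  | —              |
| heterogeneous | 0.50 | 1.5 (grainy)  | —                | 6 × ±0.30      |

The presets were chosen once so that the three classes differ along
orthogonal texture axes (first-order statistics, orientation,
heterogeneity), loosely echoing the qualitative descriptions of the
three clinical classes; no acoustic physics or clinical fidelity is
claimed. Cohorts are class-balanced by construction and byte-reproducible
from (specs, seed): every per-sample seed derives from the run seed via
`numpy.random.SeedSequence`.

What passing tests on phantoms show: the pipeline's machinery (feature
definitions, episode sampling, KNN, metrics) is correct and the feature
spaces separate textures that differ in the ways the presets differ.
What they do not show: performance on real ultrasound, whose speckle is
correlated, whose lesions are not elliptical, and whose class differences
are far subtler.

## The 33 texture features

The feature battery names five families with fixed counts (6 GH, 6 GLCM,
3 Gabor, 12 GMRF, 6 Tamura); the concrete definitions below are the
standard ones with those cardinalities, fixed as package conventions.

* **Grey histogram (6)** — mean, population variance, skewness, excess
  kurtosis over foreground pixels; energy Σp² and entropy −Σp·log₂p on a
  256-bin histogram over [0, 1]. Constant foreground → (v, 0, 0, 0, 1, 0).
* **GLCM (6)** — contrast, correlation, energy (angular second moment),
  homogeneity (inverse difference moment), entropy, dissimilarity;
  32 grey levels quantized from the foreground min–max range, distance 1,
  four offsets (0°, 45°, 90°, 135°) averaged; pairs counted only when
  both pixels are in the mask; matrices symmetrized and normalized.
  Zero-variance correlation is defined as 1; an empty co-occurrence is
  flagged and contributes the constant-patch values (0, 1, 1, 1, 0, 0).
* **Gabor (3)** — mean complex-response magnitude over foreground at
  orientations 0°/60°/120°, single scale (wavelength 8 px, σ = 4 px).
  The kernel is made zero-mean so constant patches respond 0.
* **GMRF (12)** — ordinary-least-squares estimates of the 12
  symmetric-pair interaction parameters of a fifth-order Gauss–Markov
  random field (half-plane offsets (0,1), (1,0), (1,1), (1,−1), (0,2),
  (2,0), (1,2), (2,1), (2,−1), (1,−2), (2,2), (2,−2)) on the
  mean-subtracted bounding-box patch, using only sites whose full
  neighborhood lies in the mask. Fewer than 30 usable sites or singular
  normal equations → zeros with a warning. A spectral synthesizer
  (`synthesize_gmrf`) generates fields with known parameters for
  recovery checks; at 64×64 the (0,1) = 0.2 parameter is recovered with
  bias < 0.01 and seed-to-seed s.d. ≈ 0.017.
* **Tamura (6)** — coarseness (best-size averaging over window sizes
  1..32; ties take the smallest size, so constant patches score 1),
  contrast σ/α₄^0.25, directionality (sum of squared masses of a 16-bin
  thresholded gradient-orientation histogram: 1 for one dominant
  orientation, 1/16 for isotropy, 0 with no edges — a deliberately
  simple sharpness functional), line-likeness (mean cosine of direction
  co-occurrence at distance 4), regularity 1 − 0.25·Σ(subwindow s.d. of
  the first four), roughness = coarseness + contrast. Computed on the
  foreground bounding box, which keeps the sliding-window structure
  intact at the cost of including some background near the lesion rim.

Features are shift-invariant where the definitions imply it: adding a
constant moves only the GH mean; quantization, mean subtraction and
gradients cancel it elsewhere.

## CNN embedding

Images are bilinearly resized and min–max normalized to (−1, 1) per
image (constant images map to the midpoint). The reference preprocessing
size is 331×331; desk-scale training uses 64×64, which the TinyConv
backbone (four 3×3 conv blocks of 8/16/32/64 channels, each ReLU +
2×2 max-pool, then global average pooling) reduces to a 64-d pooled
feature. The head is the fixed four-layer stack 1024 → 512 → 128 → 64,
ReLU on the first three and linear on the embedding layer — a linear
final layer keeps Euclidean geometry unsquashed. Training minimizes
softmax cross-entropy with Adam (β₁ = 0.9, β₂ = 0.999), batch 32, at
most 30 epochs, lr(e) = 0.001 × 0.1^⌊(e−1)/7⌋, early stop on validation
loss with patience 5 and best-weights restore, 80/20 stratified split,
and seeded crop (0.8–1.0), rotation (±15°), horizontal-flip (p = 0.5)
and brightness/contrast (±10 %) augmentation on the training split only.
Two-stage transfer is supported by `swap_classifier`: train on a binary
surrogate task, replace only the classifier layer, continue on the
ternary task; all other weights are retained verbatim.

The engine is a small numpy implementation (im2col convolution,
analytic backprop verified against finite differences in the tests),
which keeps the package dependency-light and every run bit-deterministic
on one CPU. Heavier pretrained backbones can be supplied through the
`Backbone` contract (grayscale inputs would be replicated to three
channels by the caller); none is bundled.

## Episodes, distance and KNN

`sample_episode` draws K support items per class without replacement
(seeded) and assigns **all** remaining pool items to the query set.
Distances are plain Euclidean on the raw vectors; an optional L2
normalization flag exists but defaults off. KNN uses k = 3 by default
(equal to K, odd, ≤ 9 support items; the choice is exposed as `--k`).
Determinism is guaranteed by fully specified tie rules: neighbors are
ranked by (distance, support index); a tied vote goes to the tied class
whose voting neighbors have the smallest mean distance, then to the
smallest class index. Handcrafted features are z-scored per dimension
with support-set statistics before distances (their units are
incommensurate); CNN embeddings are used raw.

## Evaluation

Confusion matrices count rows = true class, columns = predicted.
Per-class precision/recall/F1 use the one-vs-rest reductions with the
0/0 → 0 convention (required by degenerate rows such as a reader who
never predicts a class). Macro metrics are unweighted class means;
accuracy is trace/total, which equals macro recall exactly on balanced
queries. Display rounding is 3 decimals, half away from zero, matching
the convention of published tables; `reconstruct_predicted_totals`
inverts printed (TP, precision) pairs to per-class predicted totals
(nearest integer to TP/precision; TP = 0 classes absorb the remainder),
which is what lets the published comparison tables be recomputed exactly
from their printed values.

## Problem sizes and numerical choices

Synthetic studies use 33 images per class (the published cohort size) at
256×256, 20 seeded support draws per accuracy estimate, 200 episodes for
the KNN oracle check and 50 seeds for GMRF recovery — sizes at which the
whole suite and the acceptance script each finish in about a minute on
one CPU while keeping Monte-Carlo error small against the stated
margins. All randomness flows from explicit seeds through
`SeedSequence`; reruns are bit-identical.

## Known limitations

* The phantom generator is a texture testbed, not an ultrasound
  simulator; conclusions about real TVU performance cannot be drawn
  from it.
* The exact member statistics of the GLCM/Gabor/GMRF/Tamura families are
  package conventions chosen to match the stated family sizes; other
  implementations may choose different members and produce different
  numeric values.
* Features are 2-D only; no shape or wavelet families, and no feature
  selection.
* The bundled backbone is deliberately small; no pretrained weights are
  shipped, so absolute embedding quality depends on the surrogate
  training task.
* Single support draws are noisy; the `--repeats` option reports
  mean ± s.d. across seeded redraws, and should be used whenever a
  single-episode number would otherwise be quoted.
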