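# Methods

This note documents the models, algorithms and design choices behind
`mammocad`, a pipeline for two-class (normal vs. abnormal) mammogram
classification with hand-crafted texture features fused into a BiLSTM-CNN,
plus the synthetic phantoms used to exercise it end to end.

## Pipeline overview

```
image -> resize 224x224 -> contrast stretch -> 3x3 median -> shearlet enhance
      -> breast crop -> improved Otsu + Canny -> ROI
      -> 49 hybrid features (first-order + GLCM + GLRLM)
      -> BiLSTM-CNN (image branch) + feature fusion -> softmax
```

Every stage is deterministic; the classifier is deterministic given its
seed. Cross-validation, permutation tests and the ablation grid all derive
their randomness from a single integer seed.

## Preprocessing

*Resize* is bilinear with half-pixel centre alignment (resizing to the same
shape is the identity). *Contrast stretch* maps the occupied range linearly
onto [0, 255]; a constant image maps to zero with a warning — the choice is
arbitrary and explicit. *Median filtering* uses a 3×3 kernel with edge
replication; replication avoids introducing dark borders that would bias
the later threshold search.

### Shearlet enhancement

The enhancement operator is built on a cone-adapted, band-limited shearlet
frame: one lowpass window plus, for each dyadic scale *j* = 0…J−1, shear
directions *k* ∈ {−2ʲ…2ʲ} on each of the two frequency cones, giving
1 + Σⱼ 2(2·2ʲ+1) bands. Radial localisation uses cos² (Meyer-type) dyadic
windows in log₂-frequency, angular localisation uses cos² windows in the
shear variable; the squared windows are symmetrised under frequency
negation (so band coefficients of real images are real even on the Nyquist
rows of an even grid) and normalised pointwise so the squared magnitudes
sum to exactly 1. The frame is therefore Parseval by construction:
analysis followed by the adjoint reconstructs to ~1e−16, which is what
makes band amplification well-posed.

Enhancement multiplies the directional bands of selected scales by a gain
and reconstructs. Defaults: J = 3 scales, gain 1.5 on the two finest
scales, output rounded and clipped to 8 bits. The grid must satisfy
min(H, W) ≥ 2^(J+2) so the coarsest band is resolvable. Gains near 1.5
sharpen edges without driving typical mammographic content into clipping;
gain 1 is the identity up to rounding.

## Segmentation

*Breast cropping* keeps the largest 8-connected component above
0.05·max_value and returns its bounding-box crop with non-breast pixels
zeroed. An optional corner-anchored heuristic removes a bright pectoral
wedge (a component of the within-breast Otsu foreground that touches a top
corner and covers ≥ 2% of the breast). It is off by default and should be
enabled for MLO-style images that contain the pectoral muscle; on images
without one it can false-positive on bright texture near the corner.

*Improved Otsu.* Classical Otsu maximises between-class variance of the
gray-level histogram by exhaustive search. The improved variant weights
each pixel's histogram contribution by ``1 + α·v(x)/max(v)`` where v(x) is
the local intensity variance over a window×window neighbourhood (defaults
α = 1, window = 15). Textured structures — lesion interiors, spiculated
margins — therefore pull the threshold toward separating themselves from
smooth background, which is where a global histogram criterion is weakest.
α = 0 recovers classical Otsu exactly (this is tested against an
independent exhaustive search). The pipeline applies the threshold with
the zero bin excluded, because after breast cropping the zeroed background
field would otherwise dominate the histogram and the "optimal" split would
merely re-find the breast outline. The lowest maximising threshold is
returned on ties.

*Canny.* Gaussian smoothing (σ = 1.4), Sobel gradients, non-maximum
suppression with the gradient direction quantised to four sectors (with a
strict comparison on one side so plateau ties keep one pixel), and
dual-threshold hysteresis at 0.1·Gmax and 0.3·Gmax where Gmax is the peak
gradient magnitude. A final thinning pass removes the occasional
double-wide diagonal ridge that survives quantised NMS by dropping the
weakest pixel of any solid 2×2 block. The pipeline runs Canny on the
threshold-masked crop — the edge pass refines the binarized image — so
edges trace segmented structures rather than the breast silhouette.

*ROI extraction* closes the union of threshold mask and edge map (3×3),
takes the largest 8-connected component's bounding box, expands it by
``roi.pad`` (default 20 px) and clips to the image. The pad is a safety
margin: the thresholded core of a soft-margined mass systematically
under-covers its nominal radius. On abnormal phantoms the ROI localises
the lesion; on normal images the foreground percolates and the ROI is
essentially the breast.

## Hybrid features

Computed on the ROI crop, quantised to Ng = 32 equal-width bins over the
crop's own range (bins indexed from 1 so low-gray-level emphasis is
defined). The canonical 49-vector is:

| block | features | directions |
|---|---|---|
| first-order | mean, skewness, entropy, uniformity, smoothness | — |
| GLCM (distance 1, symmetric) | energy, entropy, contrast, homogeneity, correlation, cluster shade | 0°, 45°, 90°, 135° |
| GLRLM | SRE, LRE, LGRE, HGRE, GLN | 0°, 45°, 90°, 135° |

Entropies are base-2 with 0·log 0 = 0. Smoothness is 1 − 1/(1+σₙ²) with
σₙ the intensity SD rescaled to [0, 1]. GLCM correlation, homogeneity,
entropy and shade and the GLRLM set follow the standard Haralick/Galloway
definitions (the source formulas only name them). Degenerate cases are
defined, not fatal: constant texture reports correlation 0 and skewness 0
with warnings. Both matrix builders are verified exactly against
brute-force pair-counting / run-walking oracles.

Before fusion into the classifier the 49-vector is z-normalised with
means/SDs fitted on the training split only (mixed scales — e.g. mean vs.
energy — would otherwise dominate the fused layer).

## Classifier

A five-block convolutional front end followed by a bidirectional LSTM and
dense head (see `mammocad.nn` for the exact plan): conv 7×7 stems and
blocks of 512/256/128/64 channels with ReLU, overlapping 4×4/stride-2 max
pooling and dropout; the final 2×2×64 map is flattened to a 256-step,
1-feature sequence read by a BiLSTM with 64 hidden units per direction
(concatenated to 128); then dense 128 and a two-way softmax. The printed
224→150 first-layer reduction is not realisable by a stride-1 7×7
convolution, so conv1 is followed by a deterministic (and differentiable)
bilinear resampling of its feature maps to 150×150; every later size then
follows from floor((F−W+2P)/s)+1.

Implementation is pure numpy: im2col convolutions backed by BLAS matmuls
(numba-jitted packing), the 4×4/2 pool decomposed into two 2×2 max stages,
full BPTT through the BiLSTM, inverted dropout, and Adam
(lr 0.001, β = 0.9/0.999). All randomness — weight init, batch shuffling,
dropout masks — derives from one seed, so training is a pure function of
(data, config, seed); there is no early stopping for the same reason.
Gradients of every hand-written layer are verified against central finite
differences. Dropout follows the layer plan: 0.25 after the first two
pooling stages, 0.5 after the BiLSTM (configurable).

`channel_scale` multiplies the block widths (the 3-channel stem excluded,
as its width is tied to the gray-replicated RGB input) while preserving
all spatial sizes. The full-width model trains with batch 32 for 50
epochs; the test-scale profile used throughout CI (`PipelineConfig
.test_scale()`) is channel_scale 0.125, batch 8, 3 epochs — sizes chosen
so a 5-fold cross-validation of 100 phantoms runs in a few minutes on one
CPU while still separating the phantom classes cleanly. Prediction breaks
probability ties toward "abnormal" (the clinically safer default).

With fusion enabled the z-scored 49-vector is concatenated to the BiLSTM
output before the first dense layer (input width 128 + 49 = 177).

## Synthetic phantoms

`mammocad.synthetic` renders seeded, labelled mammogram-like images with
exact ground truth: a half-elliptical breast on dark background filled
with a smooth Gaussian random field (correlation length 8 px, 60 ± 10
gray levels — dark fatty tissue), optional bright pectoral wedge and skin
line, additive Gaussian noise (SD 5), clipped to 8 bits. Abnormal images
add a circumscribed mass: a bright plateau with sigmoid margin at a
radius drawn from 20–35 px (MIAS mass sizes scaled to 224²), peak
contrast δ (default 60), strongly heterogeneous interior (0.9·δ texture
at correlation length 1.5 px — malignant micro-heterogeneity, and the
feature that raises lesion co-occurrence contrast above background),
radial spicules at 0.5·δ and 1–2 px microcalcification specks at 0.8·δ.

Background, lesion and noise draws come from independent sub-streams of
the per-image seed, so at δ = 0 with no spicules/specks the two classes
are generated *identically* — an exact null for calibration. Per-image
seeds are stable hashes of (dataset seed, index), making subsets
reproducible. The defaults are the package's study conditions; the class
separation they produce (e.g. mean 0° GLCM contrast ≈ 3.2 in normals vs
≈ 5.0 in abnormals at δ = 60, n = 50/class) is what the separability and
learning tests measure.

What the phantoms do not emulate: scanner noise statistics, compression
artefacts, breast-density variation, overlapping fibroglandular
structure, or lesion taxonomies beyond a single mass. Passing tests show
the pipeline's machinery is correct and that it detects the class
structure the phantoms encode — not that it reaches any particular
performance on real mammograms.

A note on regimes: at low lesion contrast (δ ≲ 20) no threshold can
isolate the lesion, the ROI stays breast-wide, and the small residual
class difference in GLCM contrast is actually *negative* (abnormal
images' brighter maxima compress their background under contrast
stretching); past the localisation transition the difference is strongly
positive. The separability-vs-δ property is therefore stated and tested
on the magnitude of the class-mean difference.

## Evaluation

Metrics use "abnormal" as the positive class: accuracy, sensitivity
TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP), and F1 as their
harmonic mean. Zero-denominator ratios report 0 with a warning so a
degenerate fold cannot abort a run. Stratified k-fold assignment deals
each class round-robin after a seeded shuffle, so per-fold class counts
are within one of proportionality; folds partition the index set.
Cross-validation fits the feature normaliser and the network on training
indices only. The deterministic per-image pipeline outputs (preprocessed
stacks, feature rows) are computed once and indexed per fold — they carry
no cross-sample information, so this is not leakage.

Group comparison reports per-feature class means with either Welch's
t-test (default; the source names no test) or a seeded label-permutation
test of the absolute mean difference, with one shared row permutation per
resample across features and the add-one p-value estimate. A
zero-variance feature under Welch falls back to permutation with a
warning.

The ablation grid toggles the five named stages (contrast, median,
shearlet; Otsu, Canny). With a stage set empty the pipeline degenerates
to resize-only preprocessing and a whole-image ROI, which is the "no
preprocessing" baseline.

## Problem sizes used in CI and the acceptance script

Property tests run oracles at Ng = 4 on 8×8 images (50 per direction),
Otsu equivalence on 50 random 16×16 images, Parseval reconstruction on
64×64 grids. The phantom study runs at the default conditions
(δ = 60, 224² phantoms, n = 50/class, 5-fold, test-scale model); the
acceptance script repeats the cross-validation and ablation at
n = 30/class, its own choice of desk scale, and the separability test at
n = 50/class. The full-width (channel_scale 1.0) model is built and
introspected but not trained in CI.

## Known limitations

- The recurrent branch reads a scalar sequence (256×1), so its modelling
  capacity is limited; it follows the published plan rather than a design
  optimum.
- The pectoral heuristic assumes a corner-anchored, distinctly bright
  wedge; it is not a general pectoral segmenter.
- Quantisation over the ROI's own range makes features
  illumination-invariant but couples them to ROI extent; features from
  different segmentation configs are not directly comparable.
- The 16-bit PGM path rescales to 8 bits on load; the pipeline is
  specified for 8-bit dynamics throughout.
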