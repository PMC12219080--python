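# mammocad

Computer-aided classification of mammograms into **normal** vs
**abnormal**, combining classical texture analysis with a recurrent
convolutional network:

1. **Preprocessing** — resize to 224×224, contrast stretching, 3×3 median
   filtering, and edge enhancement in a cone-adapted *shearlet* frame
   (a Parseval frame of directional band-pass filters; amplifying the
   fine-scale bands sharpens lesion boundaries with an exactly invertible
   transform).
2. **Segmentation** — breast-field cropping, an *improved Otsu* threshold
   whose histogram is weighted by local variance
   (w(x) = 1 + α·v(x)/max v, α = 0 recovering classical Otsu), and Canny
   edge refinement (thresholds 0.1/0.3 of the peak gradient); their fused
   foreground yields the region of interest (ROI).
3. **Hybrid features** — 49 descriptors per ROI: five first-order
   statistics (mean, skewness, entropy, uniformity, smoothness), six
   gray-level co-occurrence (GLCM) features × four directions
   (energy, entropy, contrast = ΣᵢΣⱼ(i−j)²P(i,j), homogeneity,
   correlation, cluster shade), and five run-length (GLRLM) features ×
   four directions (SRE = (1/Nr)ΣΣR(i,j)/j², LRE, LGRE, HGRE, GLN).
4. **Classifier** — a 2D BiLSTM-CNN: five convolutional blocks
   (7×7…5×5 kernels, 512→64 channels, overlapping 4×4/2 max pooling),
   the final feature map reshaped to a 256-step sequence read by a
   bidirectional LSTM (128-wide output), optionally fused with the
   z-scored 49-feature vector, then dense 128 → softmax. Trained with
   Adam (lr 0.001) under categorical cross-entropy; implemented in seeded
   pure numpy, so results are bit-reproducible on any CPU.
5. **Evaluation** — stratified 5-fold cross-validation with per-fold
   accuracy/sensitivity/specificity/precision/F1 (mean ± SD), per-feature
   Welch/permutation class comparisons, and a preprocessing ablation
   grid.

Because the MIAS mammography archive cannot be redistributed, the package
ships a **seeded phantom generator** (`mammocad.synthetic`): breast-shaped
images with correlated tissue texture and, in the abnormal class,
heterogeneous bright masses with spicules and microcalcifications, plus
exact ground-truth masks. Every stage of the pipeline is testable end to
end without external data; MIAS-style PGM images and their plain-text
annotation format are supported for real-data use
(`mammocad.io_formats`).

Intended users: researchers prototyping mammography CAD pipelines,
and anyone needing reference implementations of GLCM/GLRLM texture
descriptors, variance-weighted Otsu thresholding, or band-limited
shearlet enhancement with exact reconstruction.

## Worked example

```python
from mammocad import (MammogramClassifier, PhantomParams, PipelineConfig,
                      generate_dataset)

# 40 phantoms (20 per class), CPU-scale model: 1/8-width channels
data, truth = generate_dataset(PhantomParams(), n_per_class=20, seed=0)
cfg = PipelineConfig.test_scale()
results = MammogramClassifier(data, cfg).fit(k=5, seed=0)
print(results.summary())
```

```
Mammogram BiLSTM-CNN classification (stratified 5-fold CV, seed 0)
n = 40 images, fusion = True, channel_scale = 0.125
config digest = 83a428ae45c2f6b0
----------------------------------------------------------------
metric              mean        sd
accuracy          0.9750    0.0559
sensitivity       1.0000    0.0000
specificity       0.9500    0.1118
precision         0.9600    0.0894
f1                0.9778    0.0497
```

The table reports the cross-validated means and standard deviations over
the five folds: with the default phantom contrast (δ = 60) the classes
separate almost perfectly, so accuracy/sensitivity/specificity sit near
1.0 with small fold-to-fold spread. Feature-level analysis of the same
data:

```python
from mammocad import compare_feature_groups
from mammocad.pipeline import feature_table

table = feature_table(data, cfg)
stats = compare_feature_groups(table.drop(columns=["id", "label"]),
                               table["label"], method="permutation",
                               n_perm=2000, seed=0)
print(stats.loc[["fo_mean", "glcm_contrast_d0", "glrlm_sre_d0"]].round(4))
```

```
                  mean_normal  mean_abnormal  p_value
feature
fo_mean              130.4231        73.1243   0.0005
glcm_contrast_d0       3.1806         4.5378   0.0005
glrlm_sre_d0           0.6217         0.6243   0.7616
```

`mean_normal`/`mean_abnormal` are the class means of each descriptor and
`p_value` the two-sided permutation p-value (floor 1/(n_perm+1) ≈ 0.0005
at 2000 resamples). Abnormal ROIs have a lower mean in these phantoms —
the ROI localises the lesion, and its crop spans the full local dynamic
range — and distinctly higher co-occurrence contrast, reflecting the
heterogeneous mass interior; short-run emphasis barely differs at this
sample size.

The same workflows are scriptable from the shell:

```bash
mammocad simulate --seed 0 --out artifacts/          # phantoms + manifest
mammocad features --manifest artifacts/manifest.csv --out artifacts/
mammocad evaluate --manifest artifacts/manifest.csv --out artifacts/
mammocad ablate   --manifest artifacts/manifest.csv --out artifacts/
```

Every run writes its resolved YAML config and digest next to its outputs,
and any run is bit-reproducible from that snapshot.

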