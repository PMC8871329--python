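# dermseg

Unsupervised saliency segmentation of skin lesions in dermoscopic images.

Delineating the lesion from the surrounding skin is the first step of any
computer-assisted melanoma work-up, and it is hard precisely because real
dermoscopic images are messy: hair and blood vessels cross the lesion, rigs
leave ruler marks, ink and color-calibration charts in the frame, gel bubbles
and vignettes distort the illumination, and many lesions have low contrast or
irregular, multi-shade borders. `dermseg` implements a deterministic,
training-free segmenter built on color-histogram clustering and Otsu
thresholding, together with the two classic preprocessing devices (a
razor-style hair remover and CLAHE) and a paired-t-test harness, so the
question *"does preprocessing actually help this segmenter?"* can be answered
quantitatively. A synthetic dermoscopy generator with exact ground-truth
masks makes the whole package testable without downloading any dataset.

## The algorithm

For an 8-bit RGB image of M×N pixels:

1. **Quantization.** Each channel is binned uniformly into 8 levels, giving
   every pixel a color index in [1, 512]. Pixels sharing an index form one
   cluster; the K ≤ 512 non-empty bins are the regions.
2. **Cluster features.** In jointly min–max-normalized CIELAB (D65), each
   cluster z gets its mean color, mean normalized position, weight
   w_z = |z|/MN, global color contrast
   C_z = Σ_y w_y‖Lab_z − Lab_y‖₂, and center-prior distance
   D_z = (1/n²|z|) Σ_{p∈z} [(x_p/M − ½)² + (y_p/N − ½)²],
   with 1-based pixel coordinates and scaling parameter n ∈ [0.1, 1].
3. **Saliency.** With contrast ratio Φ_zy = (C_z + 0.05)/(C_y + 0.05) and
   inter-cluster distance d_zy between mean positions,

       S_z = Σ_y w_y · Φ_zy · e^{−d_zy},
       CSS_z = e^{−D_z} · (w_z C_z + S_z),

   min–max rescaled to [0, 1] and broadcast to every pixel of the cluster.
4. **Thresholding.** Otsu's criterion (maximal between-class variance over a
   256-bin histogram) binarizes the saliency map; foreground is strictly
   above the threshold.
5. **Morphology.** Hole filling, dilation with the exact Euclidean disk of
   radius 3, and removal of components smaller than 30% of the largest one.

The entire pipeline is deterministic and needs no training data.

## Worked example

```python
import numpy as np
from dermseg import CHCOtsuSegmenter, FixtureSpec, generate, compute_metrics

img, gt = generate(FixtureSpec(seed=7, artifacts=("hair",)))
seg = CHCOtsuSegmenter(n=0.5)
mask = seg.segment(img)
m = compute_metrics(mask, gt)
print(f"clusters K        = {seg.n_clusters_}")
print(f"Otsu threshold    = {seg.threshold_:.4f}")
print(f"Dice              = {m.dice:.3f}")
```

prints

```
clusters K        = 17
Otsu threshold    = 0.0742
Dice              = 0.842
```

The 256×256 synthetic image (a darker elliptical lesion on skin-toned
background, crossed by dark hair strands) collapses into 17 color clusters;
the saliency map separates lesion from skin at the Otsu cut 0.074, and the
final mask overlaps the generator's exact ground truth with Dice 0.842 —
hair crossing the lesion costs a few points versus an artifact-free fixture
(≈ 0.94).

The estimators are scikit-learn compatible, so preprocessing composes as a
pipeline:

```python
from sklearn.pipeline import Pipeline
from dermseg import HairRemover

pipe = Pipeline([("shave", HairRemover()), ("segment", CHCOtsuSegmenter())])
masks = pipe.fit([img]).transform([img])
```

## Command line

```sh
dermseg fixtures --n 13 --seed 7 --out fixtures/          # synthetic suite
dermseg segment --input fixtures/ --output run_none/ --gt fixtures/
dermseg segment --input fixtures/ --output run_hair/ --gt fixtures/ --preprocess dullrazor
dermseg experiment --run-a run_none/metrics.csv --run-b run_hair/metrics.csv
```

`segment` writes one mask PNG per image plus a per-image metrics CSV
(accuracy, sensitivity, specificity, Dice) when ground truths are given;
`experiment` pairs two runs by image and reports two-tailed paired t-tests
for accuracy and Dice in the usual paired-table layout (per-condition mean,
SE, SD, 95% CI, then t, df, p).

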