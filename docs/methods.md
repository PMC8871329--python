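# Methods

## Model and assumptions

`dermseg` segments a dermoscopic image by treating the lesion as the
*salient* object: the region whose color is globally rare, spatially
coherent, and near the image center. The method makes three assumptions
that hold for typical dermoscopic acquisition:

1. the lesion is darker than, and chromatically distinct from, the
   surrounding skin, so its quantized-color clusters carry high global
   color contrast;
2. the lesion is framed roughly centrally, so a center prior can
   down-weight peripheral distractors (vignettes, charts, corner
   artifacts);
3. the lesion is the largest object of interest, so small isolated
   components surviving thresholding can be discarded.

Clusters are defined by a uniform 8×8×8 quantization of the RGB cube
rather than by an adaptive palette. Uniform binning is deterministic and
parameter-free and fixes the cluster space at 512 bins; adaptive
quantizers (median cut, multilevel thresholding, k-means) would couple the
cluster boundaries to each image's histogram and were deliberately not
used. The number of non-empty bins K is the automatically determined
cluster count; any K ≥ 1 is accepted (a near-uniform image can produce
fewer than 8 clusters, in which case the saliency map may be flat and the
pipeline reports "no lesion" rather than padding clusters).

Color distances are Euclidean in CIELAB (sRGB companding, D65 white
point) after a *joint* min–max rescale of the whole Lab array to [0, 1] —
a single scale for all three channels, which preserves relative distances.
A perfectly constant image is mapped to all zeros (the rescale is
otherwise undefined) and deliberately flows into the no-lesion error path.

## Saliency score

For cluster z with weight w_z, color contrast C_z, mean normalized
position p_z, and center distance D_z:

    S_z   = Σ_y w_y · Φ_zy · exp(−‖p_z − p_y‖)     (spatial/ratio term)
    CSS_z = exp(−D_z) · (w_z C_z + S_z)

with Φ_zy = (C_z + 0.05)/(C_y + 0.05). The y-sum includes y = z (a w_z
term at unit ratio and zero distance). Scores are min–max rescaled to
[0, 1]; when all scores coincide the map is set to zero everywhere so
that thresholding raises the no-lesion error instead of fabricating a
split. The exponential base is natural.

### Coordinate convention and a half-pixel caveat

All pixel coordinates are 1-based (row x ∈ [1, M], column y ∈ [1, N]);
normalized positions are x/M and y/N. The center term (x/M − ½)² is
therefore zero at x = M/2, *half a pixel off* the true grid center
(M+1)/2. Consequently 180° rotation equivariance of the saliency map is
exact only up to O(1/M): ≲ 0.01 in saliency units at 256×256, which is
why equivariance tests use a 0.02 tolerance rather than bit equality
(the final binary mask is in practice unchanged). The literal term is
kept because the worked micro-examples (e.g. mean center distance 0.25
on the 2×2 image) pin it down.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `n` | 0.5 | – | center-prior scale, legal range [0.1, 1.0]; smaller n penalizes off-center clusters more. The range is prescribed, a working value is not; the midpoint is the package default. |
| `levels` | 8 | bins/channel | quantization depth; 8 yields the 512-bin histogram the cluster stage is sized for. |
| `bins` | 256 | – | Otsu histogram resolution on [0, 1]. |
| `se_radius` | 3 | px | Euclidean-disk dilation radius (29-offset footprint). |
| `area_frac` | 0.30 | – | components below this fraction *of the largest component's area* are removed. The reference quantity is the largest component, consistent with the lesion-is-largest assumption, and is exposed as a parameter. |

## Numerical and dialect choices

* **Otsu**: candidate cuts are the 255 bin boundaries of a fixed [0, 1]
  histogram; between-class variance ω₀ω₁(μ₀−μ₁)² with bin-center means;
  ties broken by the lowest maximizing cut; binarization is strictly
  `value > threshold` (ties to background). A flat histogram (single
  occupied bin) raises the no-lesion error.
* **Morphology order**: hole filling (4-connected background flood) →
  dilation (exact Euclidean disk, not an octagonal approximation, because
  the two differ on boundary pixels) → area filter on 8-connected
  components. Filling and dilation are extensive; only the area filter
  removes pixels, and the largest component always survives.
* **Cluster bookkeeping**: non-empty bins are labelled 1..K in increasing
  bin order; the cluster table records each cluster's source bin so the
  pixel→cluster lookup is reproducible from the table alone.

## Preprocessing devices

Both devices are deterministic re-implementations of the classic
procedures, kept intentionally simple: the experiment only needs
"removes dark curvilinear artifacts" and "locally equalizes contrast" as
A/B toggles, not bit-exact clones of historical binaries.

* **Hair removal** (razor-style): per-channel grayscale closing with
  9-px line elements at 4 orientations; candidate hair where the maximal
  closing response exceeds the original by > 25 intensity levels;
  candidate components shorter than 3× the line length are rejected
  (hairs are long; the narrow extremities of a dark lesion also trigger
  the closing response but only over a few pixels — without the length
  check the shaver nibbles lesion tips, the classic razor flaw).
  Detected pixels are replaced from the nearest non-hair pixel via a
  distance transform — a deterministic simplification of bilinear
  inpainting.
* **CLAHE**: the L channel of CIELAB on an 8×8 tile grid, per-tile
  256-bin histograms clipped at `clip_limit × tile pixels` (default
  0.01) with uniform excess redistribution, CDF mappings blended
  bilinearly between tile centers; chrominance untouched. With one tile
  and no clipping this degenerates to global histogram equalization of
  the luminance, which is the independent oracle used in tests. Tile
  grid and clip limit are conventional defaults, exposed as parameters.

## Synthetic data: what it does and does not emulate

The generator renders a darker elliptical lesion (rotated, optionally
with a random low-order radial perturbation of the border and a darker
core for multi-shade lesions) on a skin-toned background
(RGB (224, 172, 150)), adds artifacts *after* the lesion, and finally
Gaussian pixel noise (σ = 2.5). The ground-truth mask is always the
exact pre-artifact lesion support, matching how expert ground truths
are drawn for public dermoscopy datasets. Frames default to 256×256,
a common dataset image size. Randomized suites draw semi-axes of
40–80 × 30–65 px, center jitter of ±12%, arbitrary rotation, border
irregularity up to 0.15, and skin/lesion contrast gaps of 50–90
intensity levels.

Artifact classes mirror the heterogeneous properties of real
dermoscopy: hair (8 dark-brown strands, quadratic Bézier arcs of 35–85%
of the frame length, 1–2 px wide, 75% opacity), reddish blood-vessel
strands, ruler ticks, an opaque ink blob, a 35% radial vignette, a gel
bubble with a darker rim, and a corner color-calibration chart. Strands
are finite arcs at random positions rather than frame-spanning chords:
real hairs are individual strands, and a border-to-border lattice
creates closed background polygons that hole filling would flood — a
failure mode with no analogue in real images.

Not emulated: real skin texture (pigment network, pores), specular
highlights, lens distortion, compression artifacts, and truly
hair-colored lesions. Passing the synthetic suites therefore
demonstrates the algorithmic contract — contrast-driven saliency,
artifact tolerance, determinism — not clinical-grade performance.

## Evaluation harness

Metrics take the lesion as positive class: accuracy, sensitivity,
specificity, Dice from per-image confusion counts (sensitivity is
reported as 0 with a flag when the ground truth is empty). The A/B
comparison uses the two-tailed paired Student t-test on per-image
differences (sample SD, df = n−1), significant at p < 0.05, with 95%
confidence intervals reported per condition arm. No multiple-testing
correction is applied. Calibration is verified by simulation: on 1000
null replicates of 50 pairs the rejection rate sits at 0.05 ± 0.02.

## Known limitations

* Very dark, high-contrast hair can out-salient the lesion: hair
  clusters then pass the Otsu cut, and strands touching the lesion
  survive the area filter as part of the lesion component. On the
  synthetic suites this costs roughly 0.15–0.2 mean Dice at the default
  hair density (the hair-removal preprocessor recovers almost all of
  it), which is the mechanism behind the measured "preprocessing helps"
  t-tests on synthetic data — harsher than on real datasets, where hair
  is usually sparser and less opaque.
* The dilation step inflates every mask by ~3 px, which bounds Dice
  from above for small lesions (boundary-to-area ratio).
* The center prior assumes rough central framing; a lesion in a far
  corner of the frame is actively penalized.
* Problem sizes in the test and acceptance suites (256×256 frames,
  50–60 images per suite, 1000 t-test replicates) are the package's
  default study scale; all quantities are recomputed at run time from
  the seed.
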