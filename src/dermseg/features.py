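"""Regional (cluster) feature extraction for histogram-clustering saliency.

After quantization, every occupied color bin becomes one cluster.  This
module accumulates per-bin statistics (mean normalized-Lab color, mean
normalized position, pixel count), then derives the three per-cluster
features that feed the saliency score:

* ``weight`` -- the fraction of image pixels in the cluster,
* ``color_contrast`` -- the weighted mean Lab distance of the cluster's
  color to every other cluster's color (global color rarity),
* ``center_dist`` -- the mean squared normalized distance of the
  cluster's pixels to the image center, scaled by ``1/n**2`` (the center
  prior: lesions tend to sit near the middle of a dermoscopic frame).

Coordinate convention (used throughout the package): ``x`` is the
1-based row in ``[1, M]`` and ``y`` the 1-based column in ``[1, N]``;
normalized positions are ``x/M`` and ``y/N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2lab

from .errors import ParameterError, ShapeError
from .quantize import validate_rgb_image

__all__ = [
    "SaliencyParams",
    "PaletteAccumulator",
    "ClusterTable",
    "rgb_to_lab",
    "rgb_to_normalized_lab",
    "accumulate_palette",
    "extract_clusters",
    "color_contrast",
    "center_prior",
]


@dataclass(frozen=True)
class SaliencyParams:
    """Tunable parameters of the saliency stage.

    Parameters
    ----------
    n : float
        Distance-scaling parameter of the center prior, legal range
        ``[0.1, 1.0]``.  Small ``n`` sharpens the prior (penalizes
        off-center clusters more).  Default 0.5, the midpoint of the
        legal range.
    epsilon : float
        Smoothing constant of the contrast ratio
        ``(C_x + eps) / (C_y + eps)``; fixed at 0.05.
    """

    n: float = 0.5
    epsilon: float = 0.05

    def __post_init__(self) -> None:
        if not (0.1 <= self.n <= 1.0):
            raise ParameterError(f"n must lie in [0.1, 1.0], got {self.n!r}")


@dataclass
class PaletteAccumulator:
    """Per-color-bin running sums over all image pixels.

    One row per quantization bin (512 rows for 8 levels/channel):
    normalized-Lab sums, 1-based coordinate sums, pixel count, and the
    1-based cluster label assigned to every non-empty bin (0 for empty
    bins).
    """

    sum_lab: np.ndarray  # (B, 3) float64
    sum_x: np.ndarray  # (B,) float64, 1-based row sums
    sum_y: np.ndarray  # (B,) float64, 1-based column sums
    pixel_count: np.ndarray  # (B,) int64
    cluster_label: np.ndarray  # (B,) int32, 0 = empty bin

    @property
    def n_bins(self) -> int:
        return self.pixel_count.shape[0]


@dataclass
class ClusterTable:
    """Features of the K non-empty color clusters of one image.

    ``bin_index`` records the 1-based quantization bin each cluster came
    from, which makes the bin -> cluster lookup reproducible from the
    table alone.
    """

    mean_lab: np.ndarray  # (K, 3) normalized Lab in [0, 1]
    mean_x: np.ndarray  # (K,) normalized row position in (0, 1]
    mean_y: np.ndarray  # (K,) normalized column position in (0, 1]
    pixel_count: np.ndarray  # (K,) int64
    weight: np.ndarray  # (K,) fraction of image, sums to 1
    bin_index: np.ndarray  # (K,) int32, 1-based source bin
    center_dist: np.ndarray = field(default=None)  # (K,) center prior distance
    color_contrast: np.ndarray = field(default=None)  # (K,) global color contrast
    saliency: np.ndarray = field(default=None)  # (K,) rescaled saliency in [0, 1]

    def __post_init__(self) -> None:
        k = self.mean_lab.shape[0]
        if self.center_dist is None:
            self.center_dist = np.zeros(k)
        if self.color_contrast is None:
            self.color_contrast = np.zeros(k)
        if self.saliency is None:
            self.saliency = np.zeros(k)

    @property
    def n_clusters(self) -> int:
        return int(self.mean_lab.shape[0])

    def label_map(self, idx: np.ndarray) -> np.ndarray:
        """Per-pixel 1-based cluster label for a quantization index map."""
        lut = np.zeros(int(idx.max()) + 1, dtype=np.int32)
        lut[self.bin_index] = np.arange(1, self.n_clusters + 1, dtype=np.int32)
        labels = lut[idx]
        if np.any(labels == 0):
            raise ValueError("index map contains bins absent from the cluster table")
        return labels


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """sRGB (D65) to CIELAB, unrescaled: L in [0, 100], a/b signed."""
    img = validate_rgb_image(img)
    return rgb2lab(img)


def rgb_to_normalized_lab(img: np.ndarray) -> np.ndarray:
    """CIELAB conversion followed by a joint min-max rescale to [0, 1].

    The rescale is global over all three channels together (a single
    min and max for the whole Lab array), so relative distances between
    colors are preserved up to one common scale factor.  Constant images
    map to all zeros.
    """
    img = validate_rgb_image(img)
    if (img == img[0, 0]).all():  # constant image: degenerate rescale
        return np.zeros(img.shape, dtype=np.float64)
    lab = rgb_to_lab(img)
    lo, hi = lab.min(), lab.max()
    if hi == lo:
        return np.zeros_like(lab)
    return (lab - lo) / (hi - lo)


def accumulate_palette(
    lab: np.ndarray, idx: np.ndarray, n_bins: int = 512
) -> PaletteAccumulator:
    """Accumulate normalized-Lab and coordinate sums per color bin.

    Coordinates are 1-based: pixel at row r (0-based) contributes
    ``r + 1`` to ``sum_x`` of its bin.  Non-empty bins are labelled
    ``1..K`` in increasing bin order.
    """
    lab = np.asarray(lab, dtype=np.float64)
    idx = np.asarray(idx)
    if lab.shape[:2] != idx.shape:
        raise ShapeError(
            f"lab {lab.shape[:2]} and index {idx.shape} spatial shapes differ"
        )
    m, n = idx.shape
    flat = idx.ravel().astype(np.intp) - 1
    if flat.min() < 0 or flat.max() >= n_bins:
        raise ValueError(f"index values must lie in [1, {n_bins}]")
    rows = np.repeat(np.arange(1, m + 1, dtype=np.float64), n)
    cols = np.tile(np.arange(1, n + 1, dtype=np.float64), m)
    sum_lab = np.stack(
        [
            np.bincount(flat, weights=lab[..., c].ravel(), minlength=n_bins)
            for c in range(3)
        ],
        axis=1,
    )
    sum_x = np.bincount(flat, weights=rows, minlength=n_bins)
    sum_y = np.bincount(flat, weights=cols, minlength=n_bins)
    count = np.bincount(flat, minlength=n_bins).astype(np.int64)
    label = np.zeros(n_bins, dtype=np.int32)
    occupied = count > 0
    label[occupied] = np.arange(1, int(occupied.sum()) + 1, dtype=np.int32)
    return PaletteAccumulator(sum_lab, sum_x, sum_y, count, label)


def extract_clusters(pal: PaletteAccumulator, m: int, n: int) -> ClusterTable:
    """Turn the non-empty palette bins into a K-row cluster table.

    Mean position is normalized before averaging: ``mean_x`` of a
    cluster is ``(sum_x / M) / count`` so it lands in ``(0, 1]``; weight
    is ``count / (M * N)``.
    """
    occupied = pal.pixel_count > 0
    count = pal.pixel_count[occupied].astype(np.int64)
    if count.size == 0:
        raise ValueError("palette has no occupied bins")
    if int(count.sum()) != m * n:
        raise ValueError("palette counts do not partition the image")
    cnt = count.astype(np.float64)
    mean_lab = pal.sum_lab[occupied] / cnt[:, None]
    mean_x = (pal.sum_x[occupied] / m) / cnt
    mean_y = (pal.sum_y[occupied] / n) / cnt
    weight = cnt / (m * n)
    bin_index = (np.flatnonzero(occupied) + 1).astype(np.int32)
    return ClusterTable(
        mean_lab=mean_lab,
        mean_x=mean_x,
        mean_y=mean_y,
        pixel_count=count,
        weight=weight,
        bin_index=bin_index,
    )


def color_contrast(clusters: ClusterTable) -> ClusterTable:
    """Weighted global color contrast of each cluster.

    ``C_x = sum_y w_y * ||Lab_x - Lab_y||_2`` over all clusters,
    including ``y = x`` (which contributes zero).  Fills
    ``clusters.color_contrast`` in place and returns the table.
    """
    diff = clusters.mean_lab[:, None, :] - clusters.mean_lab[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    clusters.color_contrast = dist @ clusters.weight
    return clusters


def center_prior(
    idx: np.ndarray, clusters: ClusterTable, params: SaliencyParams
) -> ClusterTable:
    """Mean squared normalized distance to the image center, per cluster.

    ``D_z = (1 / (n**2 * count_z)) * sum_{p in z} [(x_p/M - 0.5)**2 +
    (y_p/N - 0.5)**2]`` with 1-based pixel coordinates.  Fills
    ``clusters.center_dist`` in place and returns the table.
    """
    m, n_cols = idx.shape
    x = np.arange(1, m + 1, dtype=np.float64)[:, None] / m - 0.5
    y = np.arange(1, n_cols + 1, dtype=np.float64)[None, :] / n_cols - 0.5
    d2 = x * x + y * y  # (M, N) via broadcasting
    labels = clusters.label_map(idx).ravel() - 1
    sums = np.bincount(labels, weights=d2.ravel(), minlength=clusters.n_clusters)
    scale = params.n * params.n * clusters.pixel_count.astype(np.float64)
    clusters.center_dist = sums / scale
    return clusters
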