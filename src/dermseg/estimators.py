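"""Estimator-style front ends for the segmentation pipeline.

The package exposes its operations as scikit-learn compatible
transformers (``get_params``/``set_params``, no-op ``fit``,
``transform`` over a batch of images), so they can sit inside sklearn
pipelines and parameter searches.  The method is unsupervised and
per-image, so ``fit`` only validates parameters.

``X`` may be a single ``(M, N, 3)`` uint8 image or a sequence of such
images; ``transform`` maps each image to its output (mask or
preprocessed image) and returns a single array for a single input.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import preprocessing as pp
from .features import (
    SaliencyParams,
    accumulate_palette,
    center_prior,
    color_contrast,
    extract_clusters,
    rgb_to_normalized_lab,
)
from .quantize import quantize_image
from .saliency import cluster_saliency, pixel_saliency
from .segmentation import binary_morphology, otsu_threshold

__all__ = ["CHCOtsuSegmenter", "HairRemover", "ClaheEnhancer"]


def _as_batch(X):
    """Normalize input to (list of images, was_single flag)."""
    if isinstance(X, np.ndarray) and X.ndim == 3:
        return [X], True
    return list(X), False


class _ImageTransformer(TransformerMixin, BaseEstimator):
    def fit(self, X=None, y=None):
        self._validate_params()
        self.n_features_in_ = 0  # image-shaped input; no tabular features
        return self

    def _validate_params(self) -> None:  # pragma: no cover - overridden
        pass

    def transform(self, X):
        self.fit(X)
        batch, single = _as_batch(X)
        out = [self._transform_one(img) for img in batch]
        return out[0] if single else out

    def _transform_one(self, img):  # pragma: no cover - overridden
        raise NotImplementedError


class CHCOtsuSegmenter(_ImageTransformer):
    """Unsupervised lesion segmentation by histogram-clustering saliency.

    The pipeline per image: uniform color quantization (``levels`` per
    channel), per-cluster feature extraction in normalized CIELAB,
    saliency scoring (color contrast x contrast ratio x spatial
    proximity x center prior), Otsu thresholding of the saliency map,
    then binary morphology (hole fill, disk dilation, small-component
    removal).  Fully deterministic.

    Parameters
    ----------
    n : float, default 0.5
        Center-prior distance scaling, in [0.1, 1.0].
    levels : int, default 8
        Quantization levels per channel (8 -> up to 512 clusters).
    bins : int, default 256
        Histogram bins for Otsu thresholding.
    se_radius : int, default 3
        Radius of the Euclidean-disk structuring element.
    area_frac : float, default 0.30
        Components smaller than this fraction of the largest component
        are removed.

    Attributes (from the most recent image processed)
    -------------------------------------------------
    n_clusters_ : int
        Number of non-empty color clusters K.
    threshold_ : float
        Otsu threshold applied to the saliency map.
    """

    def __init__(self, n=0.5, levels=8, bins=256, se_radius=3, area_frac=0.30):
        self.n = n
        self.levels = levels
        self.bins = bins
        self.se_radius = se_radius
        self.area_frac = area_frac

    def _validate_params(self) -> None:
        SaliencyParams(n=self.n)  # range check

    def saliency_map(self, img: np.ndarray) -> np.ndarray:
        """The [0, 1] per-pixel saliency map of one image."""
        params = SaliencyParams(n=self.n)
        idx = quantize_image(img, self.levels)
        lab = rgb_to_normalized_lab(img)
        pal = accumulate_palette(lab, idx, n_bins=self.levels**3)
        clusters = extract_clusters(pal, *idx.shape)
        color_contrast(clusters)
        center_prior(idx, clusters, params)
        cluster_saliency(clusters, params)
        self.n_clusters_ = clusters.n_clusters
        return pixel_saliency(clusters, idx)

    def _transform_one(self, img: np.ndarray) -> np.ndarray:
        sal = self.saliency_map(img)
        self.threshold_ = otsu_threshold(sal, self.bins)
        raw = sal > self.threshold_
        return binary_morphology(raw, self.se_radius, self.area_frac)

    def segment(self, img: np.ndarray) -> np.ndarray:
        """Segment a single image; alias of ``transform`` for one input."""
        self.fit()
        return self._transform_one(img)

    # predict is a natural alias for a segmenter
    predict = _ImageTransformer.transform


class HairRemover(_ImageTransformer):
    """Razor-style dark-hair removal transformer.

    See :func:`dermseg.preprocessing.remove_hair` for the procedure and
    parameter meanings.
    """

    def __init__(self, line_length=9, n_orientations=4, diff_thresh=25):
        self.line_length = line_length
        self.n_orientations = n_orientations
        self.diff_thresh = diff_thresh

    def _transform_one(self, img):
        return pp.remove_hair(
            img, self.line_length, self.n_orientations, self.diff_thresh
        )


class ClaheEnhancer(_ImageTransformer):
    """Contrast-limited adaptive histogram equalization transformer.

    See :func:`dermseg.preprocessing.clahe_enhance`.
    """

    def __init__(self, tiles=8, clip_limit=0.01, nbins=256):
        self.tiles = tiles
        self.clip_limit = clip_limit
        self.nbins = nbins

    def _transform_one(self, img):
        return pp.clahe_enhance(img, self.tiles, self.clip_limit, self.nbins)
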