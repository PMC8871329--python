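"""Otsu thresholding of the saliency map and binary morphological cleanup.

The saliency map is a grayscale image in [0, 1] that is naturally
amenable to global histogram thresholding.  Otsu's criterion picks the
cut maximizing the between-class variance ``w0 * w1 * (mu0 - mu1)**2``
of the two resulting classes; pixels strictly above the threshold form
the raw silhouette.  Morphology then (1) fills holes, (2) dilates with
an exact Euclidean disk, and (3) drops small isolated components,
reflecting the assumption that the lesion is the largest object in a
dermoscopic frame.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk

from .errors import NoLesionError, ParameterError, ShapeError

__all__ = ["otsu_threshold", "binary_morphology", "segment"]


def otsu_threshold(sal: np.ndarray, bins: int = 256) -> float:
    """Otsu's optimal threshold for a saliency map with values in [0, 1].

    The map is histogrammed into ``bins`` equal-width bins on [0, 1];
    every bin boundary is a candidate cut, and the one maximizing the
    between-class variance is returned (ties broken by the lowest
    maximizing cut).  The binarization rule throughout the package is
    strictly ``value > threshold``.

    Raises
    ------
    NoLesionError
        If all values fall into a single histogram bin (flat map), so
        no cut produces two non-empty classes.
    """
    sal = np.asarray(sal, dtype=np.float64)
    if sal.min() < 0 or sal.max() > 1:
        raise ValueError("saliency values must lie in [0, 1]")
    if bins < 2:
        raise ParameterError(f"bins must be >= 2, got {bins!r}")
    which = np.clip(np.floor(sal.ravel() * bins).astype(np.intp), 0, bins - 1)
    hist = np.bincount(which, minlength=bins).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise NoLesionError("saliency map is flat; no threshold separates it")
    total = hist.sum()
    centers = (np.arange(bins) + 0.5) / bins
    w0 = np.cumsum(hist)[:-1]  # pixels in bins <= t, for cut after bin t
    w1 = total - w0
    m0 = np.cumsum(hist * centers)[:-1]
    m1 = m0[-1] + hist[-1] * centers[-1] - m0
    valid = (w0 > 0) & (w1 > 0)
    var_between = np.full(bins - 1, -np.inf)
    var_between[valid] = (
        w0[valid] * w1[valid] * (m0[valid] / w0[valid] - m1[valid] / w1[valid]) ** 2
    )
    t = int(np.argmax(var_between))  # argmax returns the first (lowest) maximizer
    return (t + 1) / bins


def binary_morphology(
    mask: np.ndarray, se_radius: int = 3, area_frac: float = 0.30
) -> np.ndarray:
    """Hole filling, disk dilation, and small-component removal.

    Steps, in order: background components not connected to the border
    (4-connectivity) become foreground; dilation with the exact
    Euclidean disk ``{(dx, dy): dx**2 + dy**2 <= r**2}``; connected
    components (8-connectivity) with area below ``area_frac`` times the
    area of the largest component are removed.  The largest component
    always survives, so a non-empty input yields a non-empty output.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ShapeError(f"expected a 2-D mask, got shape {mask.shape}")
    if not mask.any():
        raise NoLesionError("empty mask: nothing to post-process")
    filled = binary_fill_holes(mask)
    dilated = dilation(filled, footprint=disk(int(se_radius)))
    labels = cc_label(dilated, connectivity=2)
    areas = np.bincount(labels.ravel())[1:]  # skip background
    keep = np.flatnonzero(areas >= area_frac * areas.max()) + 1
    return np.isin(labels, keep)


def segment(img: np.ndarray, params=None, **kwargs) -> np.ndarray:
    """Full saliency segmentation of one RGB dermoscopic image.

    Thin functional wrapper over
    :class:`dermseg.estimators.CHCOtsuSegmenter`; see that class for the
    tunable parameters.  ``params`` may be a
    :class:`~dermseg.features.SaliencyParams` to set the center-prior
    scaling ``n``.

    Returns the boolean lesion mask; raises :class:`NoLesionError` on a
    flat saliency map (e.g. constant-color input).
    """
    from .estimators import CHCOtsuSegmenter

    if params is not None:
        kwargs.setdefault("n", params.n)
    return CHCOtsuSegmenter(**kwargs).segment(img)
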