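"""Uniform color quantization of 8-bit RGB images.

The segmentation pipeline opens by collapsing the RGB cube into at most
``levels**3`` dominant-color bins (512 for the default ``levels=8``), so
that every pixel carries a small integer color index.  Pixels sharing an
index form one candidate homogeneous region for the downstream
histogram-clustering stage.

Quantization is uniform fixed-width binning per channel (bin width
``256/levels``): it is deterministic, parameter-free and yields exactly
the 8x8x8 bin grid the histogram stage expects.  Data-adaptive palette
optimisation (median cut, k-means) is deliberately not used.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError, ShapeError

__all__ = ["validate_rgb_image", "quantize_image"]


def validate_rgb_image(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is an M x N x 3 array of 8-bit intensities.

    Returns the image as a C-contiguous uint8 array.  Raises
    :class:`ShapeError` for wrong dimensionality and ``ValueError`` for
    out-of-range values.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ShapeError(
            f"expected an M x N x 3 RGB image, got array of shape {img.shape}"
        )
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ShapeError("image must contain at least one pixel")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.floating):
            raise ValueError("expected integer intensities in [0, 255], got floats")
        if img.min() < 0 or img.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        img = img.astype(np.uint8)
    return np.ascontiguousarray(img)


def quantize_image(img: np.ndarray, levels: int = 8) -> np.ndarray:
    """Map every pixel to a 1-based color-bin index in ``[1, levels**3]``.

    Each channel value ``v`` falls in bin ``floor(v * levels / 256)``
    (clamped to ``levels - 1``); the three channel bins are packed
    r-major into ``bin_r * levels**2 + bin_g * levels + bin_b + 1``.

    Parameters
    ----------
    img : ndarray, shape (M, N, 3), uint8
        Input RGB image.
    levels : int
        Quantization levels per channel, in ``[2, 256]``.

    Returns
    -------
    ndarray of int32, shape (M, N)
        Per-pixel bin index, 1-based.
    """
    img = validate_rgb_image(img)
    if not (2 <= int(levels) <= 256):
        raise ParameterError(f"levels must be in [2, 256], got {levels!r}")
    levels = int(levels)
    bins = (img.astype(np.int64) * levels) // 256
    np.clip(bins, 0, levels - 1, out=bins)
    index = bins[..., 0] * levels * levels + bins[..., 1] * levels + bins[..., 2] + 1
    return index.astype(np.int32)
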