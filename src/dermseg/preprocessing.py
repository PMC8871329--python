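"""Optional preprocessing stages: hair removal and adaptive equalization.

Two classic dermoscopy preprocessing devices, provided so the
with/without-preprocessing comparison can be run:

* :func:`remove_hair` -- a razor-style dark-hair shaver: grayscale
  morphological closing with thin line elements at several orientations
  highlights dark curvilinear structures; pixels where the closing
  response exceeds the original by more than a threshold are declared
  hair and replaced from the nearest non-hair pixel.
* :func:`clahe_enhance` -- contrast-limited adaptive histogram
  equalization (CLAHE) of the Lab luminance channel: per-tile clipped
  histogram equalization with bilinear blending between tile mappings;
  chrominance is left untouched.

Both are deterministic re-implementations of the classic procedures,
intentionally simple: their contract here is "removes dark curvilinear
artifacts" / "locally equalizes contrast", which is all the A/B
preprocessing experiment requires.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.color import lab2rgb, rgb2lab
from skimage.measure import label as cc_label
from skimage.morphology import closing

from .errors import ParameterError
from .quantize import validate_rgb_image

__all__ = ["remove_hair", "clahe_enhance", "hair_mask", "line_footprint"]


def line_footprint(length: int, angle_deg: float) -> np.ndarray:
    """Boolean line structuring element of ``length`` pixels at an angle."""
    half = (length - 1) / 2.0
    t = np.arange(length) - half
    rows = np.round(t * np.sin(np.deg2rad(angle_deg))).astype(int)
    cols = np.round(t * np.cos(np.deg2rad(angle_deg))).astype(int)
    r0, c0 = rows.min(), cols.min()
    fp = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=bool)
    fp[rows - r0, cols - c0] = True
    return fp


def hair_mask(
    img: np.ndarray,
    line_length: int = 9,
    n_orientations: int = 4,
    diff_thresh: float = 25,
    min_component: int | None = None,
) -> np.ndarray:
    """Boolean mask of dark curvilinear (hair-like) pixels.

    Per channel, grayscale closing with line elements at
    ``n_orientations`` evenly spaced angles; a pixel is a hair candidate
    where the maximum closing response exceeds the original value by
    more than ``diff_thresh`` intensity levels in any channel.
    Candidate components shorter than ``min_component`` pixels (default
    ``3 * line_length``) are rejected: hairs are long structures, while
    the narrow extremities of a dark lesion also trigger the closing
    response but only over a few pixels.
    """
    img = validate_rgb_image(img)
    if min_component is None:
        min_component = 3 * line_length
    angles = np.arange(n_orientations) * (180.0 / n_orientations)
    response = np.zeros(img.shape[:2], dtype=np.int16)
    for angle in angles:
        fp = line_footprint(line_length, angle)
        for c in range(3):
            closed = closing(img[..., c], footprint=fp)
            diff = closed.astype(np.int16) - img[..., c].astype(np.int16)
            np.maximum(response, diff, out=response)
    cand = response > diff_thresh
    labels = cc_label(cand, connectivity=2)
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_component)
    cand[np.isin(labels, small[small > 0])] = False
    return cand


def remove_hair(
    img: np.ndarray,
    line_length: int = 9,
    n_orientations: int = 4,
    diff_thresh: float = 25,
) -> np.ndarray:
    """Shave dark hair strokes: detect, then inpaint from nearest skin.

    Detected hair pixels are replaced by the RGB value of the nearest
    non-hair pixel (Euclidean distance transform), a deterministic
    simplification of the classic bilinear inpainting.  A hair-free
    image is returned unchanged.
    """
    img = validate_rgb_image(img)
    mask = hair_mask(img, line_length, n_orientations, diff_thresh)
    if not mask.any() or mask.all():
        return img.copy()
    _, (ir, ic) = distance_transform_edt(mask, return_indices=True)
    out = img.copy()
    out[mask] = img[ir[mask], ic[mask]]
    return out


def clahe_enhance(
    img: np.ndarray, tiles: int = 8, clip_limit: float = 0.01, nbins: int = 256
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of luminance.

    The L channel of CIELAB (scaled to [0, 1]) is split into a
    ``tiles x tiles`` grid of contextual regions.  Each region's
    ``nbins``-bin histogram is clipped at ``clip_limit * (region pixel
    count)`` with the excess redistributed uniformly, and turned into a
    CDF mapping.  Every pixel is remapped by bilinear interpolation
    between the mappings of the four nearest tile centers; a and b
    chrominance channels pass through unchanged.

    ``tiles=1`` with ``clip_limit=1`` degenerates to plain global
    histogram equalization of the luminance channel.
    """
    img = validate_rgb_image(img)
    m, n = img.shape[:2]
    if tiles < 1 or m < tiles or n < tiles:
        raise ParameterError(
            f"tile grid {tiles}x{tiles} does not fit a {m}x{n} image"
        )
    lab = rgb2lab(img)
    lum = np.clip(lab[..., 0] / 100.0, 0.0, 1.0)
    bins_img = np.clip((lum * nbins).astype(np.intp), 0, nbins - 1)

    row_edges = np.round(np.linspace(0, m, tiles + 1)).astype(int)
    col_edges = np.round(np.linspace(0, n, tiles + 1)).astype(int)
    centers_r = (row_edges[:-1] + row_edges[1:] - 1) / 2.0
    centers_c = (col_edges[:-1] + col_edges[1:] - 1) / 2.0

    mappings = np.empty((tiles, tiles, nbins))
    for i in range(tiles):
        for j in range(tiles):
            tile = bins_img[row_edges[i] : row_edges[i + 1],
                            col_edges[j] : col_edges[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=nbins).astype(np.float64)
            limit = clip_limit * tile.size
            excess = np.clip(hist - limit, 0, None).sum()
            hist = np.minimum(hist, limit) + excess / nbins
            mappings[i, j] = np.cumsum(hist) / hist.sum()

    fi = np.interp(np.arange(m), centers_r, np.arange(tiles))
    fj = np.interp(np.arange(n), centers_c, np.arange(tiles))
    i0 = np.floor(fi).astype(int)
    j0 = np.floor(fj).astype(int)
    i1 = np.minimum(i0 + 1, tiles - 1)
    j1 = np.minimum(j0 + 1, tiles - 1)
    a = (fi - i0)[:, None]
    b = (fj - j0)[None, :]
    i0c, i1c = i0[:, None], i1[:, None]
    j0c, j1c = j0[None, :], j1[None, :]
    new_lum = (
        (1 - a) * (1 - b) * mappings[i0c, j0c, bins_img]
        + (1 - a) * b * mappings[i0c, j1c, bins_img]
        + a * (1 - b) * mappings[i1c, j0c, bins_img]
        + a * b * mappings[i1c, j1c, bins_img]
    )
    lab_out = lab.copy()
    lab_out[..., 0] = new_lum * 100.0
    rgb = lab2rgb(lab_out)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
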