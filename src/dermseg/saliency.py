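"""Cluster saliency scores and their broadcast to a per-pixel map.

Each cluster's saliency combines four cues: its global color contrast,
the contrast ratio to every other cluster, the spatial proximity of the
clusters (nearby high-contrast clusters reinforce each other), and the
center prior.  For cluster ``x``::

    S_x   = sum_y  w_y * Phi_xy * exp(-Ds_xy)
    CSS_x = exp(-D_x) * (w_x * C_x + S_x)

where ``Phi_xy = (C_x + eps) / (C_y + eps)`` is the smoothed contrast
ratio, ``Ds_xy`` the Euclidean distance between mean normalized cluster
positions, ``D_x`` the center-prior distance, ``w`` the cluster weights
and ``C`` the color contrasts.  The ``y`` sum includes ``y = x`` (a
``w_x`` term at zero distance and unit ratio).  Scores are then min-max
rescaled to ``[0, 1]`` and every pixel inherits its cluster's score.

Degenerate case: if all scores coincide (in particular K = 1) the
rescale is undefined; the map is set to all zeros so that downstream
Otsu thresholding raises the deliberate "no lesion" error.
"""

from __future__ import annotations

import numpy as np

from .features import ClusterTable, SaliencyParams

__all__ = ["cluster_saliency", "pixel_saliency", "raw_scores"]


def raw_scores(clusters: ClusterTable, params: SaliencyParams = SaliencyParams()) -> np.ndarray:
    """Per-cluster saliency scores before the final min-max rescale."""
    w = clusters.weight
    c = clusters.color_contrast
    eps = params.epsilon
    pos = np.stack([clusters.mean_x, clusters.mean_y], axis=1)
    diff = pos[:, None, :] - pos[None, :, :]
    ds = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    phi = (c[:, None] + eps) / (c[None, :] + eps)
    s = (phi * np.exp(-ds)) @ w
    return np.exp(-clusters.center_dist) * (w * c + s)


def cluster_saliency(
    clusters: ClusterTable, params: SaliencyParams = SaliencyParams()
) -> ClusterTable:
    """Compute and min-max rescale per-cluster saliency scores.

    Requires ``color_contrast`` and ``center_dist`` to be populated.
    Fills ``clusters.saliency`` in place and returns the table.
    """
    css = raw_scores(clusters, params)
    lo, hi = css.min(), css.max()
    if hi == lo:
        clusters.saliency = np.zeros_like(css)
    else:
        clusters.saliency = (css - lo) / (hi - lo)
    return clusters


def pixel_saliency(clusters: ClusterTable, idx: np.ndarray) -> np.ndarray:
    """Broadcast cluster saliency to every pixel of the index map.

    Returns an (M, N) float map in [0, 1] with at most K distinct
    values; pixels of one cluster all share that cluster's score.
    """
    labels = clusters.label_map(idx)
    return clusters.saliency[labels - 1]
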