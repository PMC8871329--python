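import numpy as np
import pytest

from dermseg.estimators import CHCOtsuSegmenter
from dermseg.features import (
    SaliencyParams,
    accumulate_palette,
    center_prior,
    color_contrast,
    extract_clusters,
    rgb_to_normalized_lab,
)
from dermseg.quantize import quantize_image


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_image(rng, max_side=4):
    """A tiny random RGB image (at most max_side x max_side)."""
    m = int(rng.integers(1, max_side + 1))
    n = int(rng.integers(1, max_side + 1))
    return rng.integers(0, 256, size=(m, n, 3), dtype=np.uint8)


def cluster_table_for(img, n=0.5, levels=8):
    """Run the feature pipeline up to the populated ClusterTable."""
    params = SaliencyParams(n=n)
    idx = quantize_image(img, levels)
    lab = rgb_to_normalized_lab(img)
    pal = accumulate_palette(lab, idx, n_bins=levels**3)
    clusters = extract_clusters(pal, *idx.shape)
    color_contrast(clusters)
    center_prior(idx, clusters, params)
    return idx, clusters


@pytest.fixture
def segmenter():
    return CHCOtsuSegmenter()
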