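import math

import numpy as np
import pytest

from dermseg.features import ClusterTable, SaliencyParams
from dermseg.saliency import cluster_saliency, pixel_saliency, raw_scores

from conftest import cluster_table_for, random_image
from oracles import naive_chc


def two_cluster_table(w, ccc, pos, pdc):
    k = len(w)
    t = ClusterTable(
        mean_lab=np.zeros((k, 3)),
        mean_x=np.array([p[0] for p in pos], dtype=float),
        mean_y=np.array([p[1] for p in pos], dtype=float),
        pixel_count=np.array([1] * k),
        weight=np.array(w, dtype=float),
        bin_index=np.arange(1, k + 1, dtype=np.int32),
    )
    t.color_contrast = np.array(ccc, dtype=float)
    t.center_dist = np.array(pdc, dtype=float)
    return t


def test_two_cluster_hand_expansion():
    """CSS matches a symbolic expansion of the two-term sum, including the
    contrast ratio (0.15 + 0.05)/(0.05 + 0.05) = 2 and the self term
    Phi_xx = 1; the rescale maps the pair onto {0, 1}."""
    w = [0.5, 0.5]
    ccc = [0.15, 0.05]
    pos = [(0.3, 0.4), (0.7, 0.6)]
    pdc = [0.2, 0.8]
    t = two_cluster_table(w, ccc, pos, pdc)
    ds = math.hypot(0.4, 0.2)
    phi_01 = (0.15 + 0.05) / (0.05 + 0.05)
    assert phi_01 == 2.0
    s0 = 0.5 * 1.0 * 1.0 + 0.5 * phi_01 * math.exp(-ds)
    s1 = 0.5 * (1 / phi_01) * math.exp(-ds) + 0.5 * 1.0 * 1.0
    css0 = math.exp(-0.2) * (0.5 * 0.15 + s0)
    css1 = math.exp(-0.8) * (0.5 * 0.05 + s1)
    np.testing.assert_allclose(raw_scores(t), [css0, css1], rtol=1e-12)
    cluster_saliency(t)
    assert set(np.round(t.saliency, 12)) == {0.0, 1.0}


def test_self_ratio_is_one(rng):
    img = random_image(rng, max_side=5)
    _, clusters = cluster_table_for(img)
    c = clusters.color_contrast
    phi = (c[:, None] + 0.05) / (c[None, :] + 0.05)
    np.testing.assert_allclose(np.diag(phi), 1.0)


def test_rescaled_scores_attain_0_and_1(rng):
    for _ in range(10):
        img = random_image(rng, max_side=5)
        idx, clusters = cluster_table_for(img)
        cluster_saliency(clusters)
        if clusters.n_clusters >= 2:
            assert clusters.saliency.min() == 0.0
            assert clusters.saliency.max() == 1.0


def test_single_cluster_gives_flat_zero_map():
    img = np.full((4, 4, 3), 50, dtype=np.uint8)
    idx, clusters = cluster_table_for(img)
    cluster_saliency(clusters)
    sal = pixel_saliency(clusters, idx)
    assert (sal == 0).all()


def test_two_cluster_map_contains_exactly_0_and_1():
    img = np.zeros((4, 4, 3), dtype=np.uint8)
    img[2:] = 255
    idx, clusters = cluster_table_for(img)
    cluster_saliency(clusters)
    sal = pixel_saliency(clusters, idx)
    assert set(sal.ravel()) == {0.0, 1.0}


def test_pixel_map_matches_naive_lookup(rng):
    img = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
    idx, clusters = cluster_table_for(img)
    cluster_saliency(clusters)
    sal = pixel_saliency(clusters, idx)
    ref = naive_chc(img)
    np.testing.assert_allclose(sal, ref["saliency_map"], atol=1e-12)
    assert len(np.unique(sal)) <= clusters.n_clusters


def test_cluster_relabeling_leaves_pixel_map_unchanged(rng):
    img = rng.integers(0, 256, size=(6, 6, 3), dtype=np.uint8)
    idx, clusters = cluster_table_for(img)
    cluster_saliency(clusters)
    base = pixel_saliency(clusters, idx)
    perm = rng.permutation(clusters.n_clusters)
    shuffled = ClusterTable(
        mean_lab=clusters.mean_lab[perm],
        mean_x=clusters.mean_x[perm],
        mean_y=clusters.mean_y[perm],
        pixel_count=clusters.pixel_count[perm],
        weight=clusters.weight[perm],
        bin_index=clusters.bin_index[perm],
        center_dist=clusters.center_dist[perm],
        color_contrast=clusters.color_contrast[perm],
        saliency=clusters.saliency[perm],
    )
    np.testing.assert_array_equal(pixel_saliency(shuffled, idx), base)


def test_saliency_map_rotates_with_the_image(segmenter):
    """180-degree equivariance. The center-prior term uses 1-based
    coordinates, whose half-pixel offset breaks exact symmetry by
    O(1/M); at realistic image sizes the deviation is below 0.02."""
    from dermseg.synthetic import FixtureSpec, generate

    img, _ = generate(FixtureSpec(seed=8, artifacts=("hair",)))
    sal = segmenter.saliency_map(img)
    sal_rot = segmenter.saliency_map(img[::-1, ::-1].copy())
    np.testing.assert_allclose(sal_rot, sal[::-1, ::-1], atol=0.02)


def test_increasing_center_distance_cannot_raise_raw_score(rng):
    img = rng.integers(0, 256, size=(6, 6, 3), dtype=np.uint8)
    _, clusters = cluster_table_for(img)
    base = raw_scores(clusters)
    j = int(rng.integers(clusters.n_clusters))
    clusters.center_dist = clusters.center_dist.copy()
    clusters.center_dist[j] += 0.7
    bumped = raw_scores(clusters)
    assert bumped[j] <= base[j]
    mask = np.arange(clusters.n_clusters) != j
    np.testing.assert_allclose(bumped[mask], base[mask])
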