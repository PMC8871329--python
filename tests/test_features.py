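import numpy as np
import pytest

from dermseg.features import (
    SaliencyParams,
    accumulate_palette,
    center_prior,
    color_contrast,
    extract_clusters,
    rgb_to_lab,
    rgb_to_normalized_lab,
)
from dermseg.errors import ParameterError
from dermseg.quantize import quantize_image

from conftest import cluster_table_for, random_image
from oracles import naive_chc


class TestLabConversion:
    def test_white_maps_to_l100_a0_b0_before_rescale(self):
        img = np.full((2, 2, 3), 255, dtype=np.uint8)
        lab = rgb_to_lab(img)
        np.testing.assert_allclose(lab[0, 0], [100.0, 0.0, 0.0], atol=0.01)

    def test_constant_image_rescales_to_zeros(self):
        img = np.full((3, 5, 3), 77, dtype=np.uint8)
        assert (rgb_to_normalized_lab(img) == 0).all()

    def test_nonconstant_image_attains_0_and_1(self, rng):
        img = rng.integers(0, 256, size=(6, 6, 3), dtype=np.uint8)
        lab = rgb_to_normalized_lab(img)
        assert lab.min() == 0.0 and lab.max() == 1.0


class TestPaletteAccumulation:
    def test_uniform_image_fills_one_bin(self):
        img = np.full((4, 5, 3), 130, dtype=np.uint8)
        idx = quantize_image(img)
        pal = accumulate_palette(rgb_to_normalized_lab(img), idx)
        assert (pal.pixel_count > 0).sum() == 1
        assert pal.pixel_count.sum() == 20

    def test_two_column_image_hand_accumulation(self):
        # left column color A, right column color B, 2x2 image
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[:, 1] = 255
        idx = quantize_image(img)
        pal = accumulate_palette(rgb_to_normalized_lab(img), idx)
        occ = np.flatnonzero(pal.pixel_count)
        assert len(occ) == 2
        np.testing.assert_array_equal(pal.pixel_count[occ], [2, 2])
        left = occ[0]  # bin 1 = black = left column
        assert pal.sum_y[left] == 1 + 1  # both left pixels are column 1
        assert pal.sum_x[left] == 1 + 2

    def test_counts_partition_the_image(self, rng):
        img = random_image(rng, max_side=6)
        pal = accumulate_palette(rgb_to_normalized_lab(img), quantize_image(img))
        assert pal.pixel_count.sum() == img.shape[0] * img.shape[1]
        occupied = pal.pixel_count > 0
        assert (pal.cluster_label[occupied] > 0).all()
        assert (pal.cluster_label[~occupied] == 0).all()


class TestClusterExtraction:
    def test_uniform_image_single_cluster(self):
        img = np.full((4, 4, 3), 10, dtype=np.uint8)
        _, clusters = cluster_table_for(img)
        assert clusters.n_clusters == 1
        np.testing.assert_allclose(clusters.weight, [1.0])

    def test_half_and_half_weights_and_positions(self):
        # 4x4, top half one color, bottom half another
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[2:] = 255
        _, clusters = cluster_table_for(img)
        assert clusters.n_clusters == 2
        np.testing.assert_allclose(clusters.weight, [0.5, 0.5])
        # top cluster rows are 1 and 2 -> mean of {1/4, 2/4} = 0.375
        np.testing.assert_allclose(clusters.mean_x, [0.375, 0.875])

    def test_weights_sum_to_one(self, rng):
        for _ in range(10):
            img = random_image(rng, max_side=6)
            _, clusters = cluster_table_for(img)
            assert clusters.weight.sum() == pytest.approx(1.0, abs=1e-9)
            assert (clusters.mean_x > 0).all() and (clusters.mean_x <= 1).all()
            assert (clusters.mean_y > 0).all() and (clusters.mean_y <= 1).all()


class TestColorContrast:
    def test_single_cluster_has_zero_contrast(self):
        img = np.full((3, 3, 3), 200, dtype=np.uint8)
        _, clusters = cluster_table_for(img)
        np.testing.assert_allclose(clusters.color_contrast, [0.0])

    def test_two_equal_weight_clusters(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[:, 1] = 255
        _, clusters = cluster_table_for(img)
        d = np.linalg.norm(clusters.mean_lab[0] - clusters.mean_lab[1])
        np.testing.assert_allclose(clusters.color_contrast, [0.5 * d, 0.5 * d])

    def test_translation_invariance_in_lab(self, rng):
        img = random_image(rng, max_side=6)
        _, clusters = cluster_table_for(img)
        base = clusters.color_contrast.copy()
        clusters.mean_lab = clusters.mean_lab + np.array([0.3, -0.1, 0.2])
        color_contrast(clusters)
        np.testing.assert_allclose(clusters.color_contrast, base, atol=1e-12)

    def test_linear_scaling_with_lab(self, rng):
        img = random_image(rng, max_side=6)
        _, clusters = cluster_table_for(img)
        base = clusters.color_contrast.copy()
        clusters.mean_lab = clusters.mean_lab * 2.5
        color_contrast(clusters)
        np.testing.assert_allclose(clusters.color_contrast, 2.5 * base, rtol=1e-12)


class TestCenterPrior:
    def test_2x2_uniform_image_mean_center_distance(self):
        # coordinates (1,1),(1,2),(2,1),(2,2): distances 0, .25, .25, .5
        img = np.full((2, 2, 3), 99, dtype=np.uint8)
        idx, clusters = cluster_table_for(img, n=1.0)
        np.testing.assert_allclose(clusters.center_dist, [0.25])

    def test_central_single_pixel_cluster_has_zero_distance(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0, 0] = 255  # 1-based (1,1) = (M/2, N/2) for M = N = 2
        idx, clusters = cluster_table_for(img, n=1.0)
        white = int(np.argmax(clusters.mean_lab[:, 0]))
        assert clusters.center_dist[white] == pytest.approx(0.0, abs=1e-15)

    def test_halving_n_quadruples_distance(self, rng):
        img = random_image(rng, max_side=6)
        _, c_half = cluster_table_for(img, n=0.5)
        _, c_full = cluster_table_for(img, n=1.0)
        np.testing.assert_allclose(c_half.center_dist, 4 * c_full.center_dist, rtol=1e-12)

    def test_grid_total_invariant_under_180_degree_rotation(self, rng):
        # sum_z count_z * PDC_z = (total squared center distance)/n^2 is an
        # exact grid invariant; per-cluster PDC is only asymptotically
        # rotation-invariant because of the 1-based half-pixel offset.
        img = rng.integers(0, 256, size=(5, 7, 3), dtype=np.uint8)
        _, a = cluster_table_for(img)
        _, b = cluster_table_for(img[::-1, ::-1].copy())
        np.testing.assert_allclose(
            (a.pixel_count * a.center_dist).sum(),
            (b.pixel_count * b.center_dist).sum(),
            rtol=1e-10,
        )

    def test_n_outside_legal_range_rejected(self):
        with pytest.raises(ParameterError):
            SaliencyParams(n=0.05)
        with pytest.raises(ParameterError):
            SaliencyParams(n=1.5)


def test_all_cluster_statistics_match_naive_loops(rng):
    """Vectorized pipeline equals the literal per-pixel reference."""
    for _ in range(10):
        img = random_image(rng, max_side=4)
        _, clusters = cluster_table_for(img)
        ref = naive_chc(img)
        np.testing.assert_array_equal(clusters.bin_index, ref["bin_index"])
        np.testing.assert_allclose(clusters.mean_lab, ref["mean_lab"], atol=1e-12)
        np.testing.assert_allclose(clusters.mean_x, ref["mean_x"], atol=1e-12)
        np.testing.assert_allclose(clusters.weight, ref["weight"], atol=1e-12)
        np.testing.assert_allclose(
            clusters.color_contrast, ref["color_contrast"], atol=1e-12
        )
        np.testing.assert_allclose(clusters.center_dist, ref["center_dist"], atol=1e-12)
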