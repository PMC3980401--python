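import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from skinmil import (RasterImage, Region, bipartition, build_pixel_graph,
                     min_covering_rect, ncut_value, segment_hierarchy,
                     segment_image)
from skinmil.segmentation import Partition


def brute_force_ncut_min(W):
    """Exhaustive minimum Ncut over all non-trivial bipartitions (oracle)."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    d = W.sum(axis=1)
    best = np.inf
    for bits in itertools.product([0, 1], repeat=n - 1):
        ind = np.array((1,) + bits, dtype=bool)
        if ind.all():
            continue
        assoc_a, assoc_b = d[ind].sum(), d[~ind].sum()
        if assoc_a <= 0 or assoc_b <= 0:
            continue
        cut = W[np.ix_(ind, ~ind)].sum()
        best = min(best, cut / assoc_a + cut / assoc_b)
    return best


def two_cluster_graph(rng, n):
    """Random graph with two dense clusters joined by one weak edge."""
    k = n // 2
    W = np.zeros((n, n))
    for block in (slice(0, k), slice(k, n)):
        size = block.stop - block.start
        w = rng.uniform(0.5, 1.0, size=(size, size))
        W[block, block] = (w + w.T) / 2
    np.fill_diagonal(W, 0.0)
    W[0, k] = W[k, 0] = rng.uniform(0.001, 0.02)
    return W


class TestBuildPixelGraph:
    def test_vertical_pair_edge_weight_formula(self):
        # 2x2 image, radius 1.2: only the 4 axis-aligned pairs get edges;
        # check the (0,0)-(1,0) weight against the closed form
        px = np.zeros((2, 2, 3))
        px[1, :] = 0.3
        g = build_pixel_graph(RasterImage(id="x", pixels=px),
                              sigma_i=0.2, sigma_x=2.0, radius=1.2)
        w = g.weights[0, 2]  # vertex 0 = (0,0), vertex 2 = (1,0)
        expected = np.exp(-(3 * 0.3 ** 2) / 0.2 ** 2) * np.exp(-1.0 / 2.0 ** 2)
        assert w == pytest.approx(expected)
        assert g.weights[2, 0] == pytest.approx(expected)
        assert g.weights.diagonal().sum() == 0.0
        assert (g.weights.toarray() > 0).sum() == 8  # 4 undirected edges

    def test_radius_one_admits_no_pairs(self):
        img = RasterImage(id="x", pixels=np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="empty graph"):
            build_pixel_graph(img, radius=1.0)

    def test_uniform_image_four_neighbour_lattice(self):
        # radius 1.2 < sqrt(2): only the 4-neighbourhood survives
        img = RasterImage(id="x", pixels=np.full((3, 3, 3), 0.5))
        g = build_pixel_graph(img, sigma_i=0.1, sigma_x=4.0, radius=1.2)
        W = g.weights.toarray()
        expected_w = np.exp(-1.0 / 16.0)
        n_edges = (W > 0).sum() // 2
        assert n_edges == 12  # 4-neighbour lattice on 3x3
        assert np.allclose(W[W > 0], expected_w)


class TestNcutValue:
    def test_disconnected_split_is_zero(self):
        W = sp.csr_matrix(np.array([[0, 1, 0, 0], [1, 0, 0, 0],
                                    [0, 0, 0, 1], [0, 0, 1, 0]], dtype=float))
        part = Partition(indicator=np.array([True, True, False, False]))
        assert ncut_value(W, part) == 0.0

    def test_two_vertices_single_edge_is_two(self):
        W = sp.csr_matrix(np.array([[0.0, 0.7], [0.7, 0.0]]))
        part = Partition(indicator=np.array([True, False]))
        assert ncut_value(W, part) == pytest.approx(2.0)

    def test_matches_hand_expansion_on_toy_graph(self):
        W = np.array([[0, 2, 1, 0], [2, 0, 0, 1],
                      [1, 0, 0, 3], [0, 1, 3, 0]], dtype=float)
        part = Partition(indicator=np.array([True, True, False, False]))
        # cut = 1 + 1 = 2; assoc(A) = 3 + 3; assoc(B) = 4 + 4
        assert ncut_value(sp.csr_matrix(W), part) == pytest.approx(2 / 6 + 2 / 8)

    def test_symmetric_in_sides(self, rng):
        W = rng.uniform(0, 1, size=(6, 6))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        Ws = sp.csr_matrix(W)
        ind = np.array([True, False, True, False, True, False])
        a = ncut_value(Ws, Partition(indicator=ind))
        b = ncut_value(Ws, Partition(indicator=~ind))
        assert a == pytest.approx(b)
        assert 0 <= a <= 2

    def test_empty_side_rejected(self):
        W = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            ncut_value(W, Partition(indicator=np.array([True, True])))


class TestBipartition:
    def test_recovers_two_clusters_exactly(self, rng):
        W = two_cluster_graph(rng, 10)
        part = bipartition(sp.csr_matrix(W))
        sides = np.sort(part.indicator.nonzero()[0])
        assert (np.array_equal(sides, np.arange(5))
                or np.array_equal(np.sort((~part.indicator).nonzero()[0]),
                                  np.arange(5)))
        assert part.value == pytest.approx(brute_force_ncut_min(W), rel=1e-9)

    def test_disconnected_components_give_zero(self):
        W = np.zeros((6, 6))
        W[0, 1] = W[1, 2] = W[0, 2] = 1.0
        W[3, 4] = W[4, 5] = W[3, 5] = 1.0
        W = W + W.T
        part = bipartition(sp.csr_matrix(W))
        assert part.value == 0.0
        labels = part.indicator
        assert labels[:3].all() != labels[3:].all() or (
            labels[:3].sum() in (0, 3) and labels[3:].sum() in (0, 3))

    def test_complete_graph_matches_brute_force(self):
        W = np.ones((4, 4)) - np.eye(4)
        part = bipartition(sp.csr_matrix(W))
        assert part.value == pytest.approx(brute_force_ncut_min(W), rel=1e-9)


class TestSegmentImage:
    def test_p_one_returns_whole_image(self):
        img = RasterImage(id="x", pixels=np.full((6, 8, 3), 0.5))
        regions = segment_image(img, 1)
        assert len(regions) == 1
        assert regions[0].n_pixels == 48

    def test_black_white_halves_recovered(self):
        px = np.zeros((20, 30, 3))
        px[:, 15:] = 1.0
        img = RasterImage(id="halves", pixels=px)
        regions = segment_image(img, 2)
        assert len(regions) == 2
        truth = np.zeros((20, 30), dtype=int)
        truth[:, 15:] = 1
        labels = np.zeros((20, 30), dtype=int)
        for k, reg in enumerate(regions):
            labels[reg.pixel_set[:, 0], reg.pixel_set[:, 1]] = k
        agree = max(np.mean(labels == truth), np.mean(labels == 1 - truth))
        assert agree >= 0.99

    @pytest.mark.parametrize("p", [1, 4, 8])
    def test_partition_property(self, small_images, p):
        images, _ = small_images
        for img in images[:2]:
            regions = segment_image(img, p)
            assert len(regions) == p
            seen = np.zeros((img.height, img.width), dtype=int)
            for reg in regions:
                seen[reg.pixel_set[:, 0], reg.pixel_set[:, 1]] += 1
            assert np.all(seen == 1)  # disjoint and covering

    def test_p_exceeding_pixels_raises(self):
        img = RasterImage(id="x", pixels=np.zeros((2, 2, 3)))
        with pytest.raises(ValueError):
            segment_image(img, 5)

    def test_hierarchy_matches_single_runs(self, small_images):
        images, _ = small_images
        img = images[0]
        hier = segment_hierarchy(img, [4, 6])
        single = segment_image(img, 6)
        hier_sets = sorted(tuple(map(tuple, r.pixel_set)) for r in hier[6])
        single_sets = sorted(tuple(map(tuple, r.pixel_set)) for r in single)
        assert hier_sets == single_sets


class TestMinCoveringRect:
    def test_rectangular_region_has_no_padding(self):
        rows, cols = np.mgrid[2:5, 3:7]
        pixel_set = np.column_stack([rows.ravel(), cols.ravel()])
        colors = np.full((pixel_set.shape[0], 3), 0.5)
        reg = min_covering_rect(Region(image_id="x", pixel_set=pixel_set,
                                       colors=colors))
        assert reg.rect.shape == (3, 4, 3)
        assert reg.mask.all()
        assert np.allclose(reg.rect, 0.5)

    def test_l_shape_pads_missing_corner(self):
        pixel_set = np.array([(r, c) for r in range(3) for c in range(3)
                              if not (r == 0 and c == 2)])
        colors = np.full((8, 3), 0.9)
        reg = min_covering_rect(Region(image_id="x", pixel_set=pixel_set,
                                       colors=colors))
        assert reg.rect.shape == (3, 3, 3)
        assert reg.mask.sum() == 8
        assert not reg.mask[0, 2]
        assert np.all(reg.rect[0, 2] == 0.0)  # padding is exactly black

    def test_single_pixel(self):
        reg = min_covering_rect(Region(image_id="x", pixel_set=[(5, 7)],
                                       colors=[[0.2, 0.4, 0.6]]))
        assert reg.rect.shape == (1, 1, 3)
        assert reg.mask.all()
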