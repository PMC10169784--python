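"""Smoothing, thinning, and skeleton-to-graph conversion."""

import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt, label as cc_label

from chdseg.skeleton import (VesselPoolVanishedError, candidate_graphs,
                             extract_graph, skeletonize, smooth_mask)


def cylinder(length=40, radius=4, shape=(40, 20, 20)):
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    m = np.zeros(shape, bool)
    m[(yy - shape[1] // 2) ** 2 + (xx - shape[2] // 2) ** 2 <= radius ** 2] = True
    m[length:] = False
    return m


class TestSmoothMask:
    def test_interior_voxel_survives(self):
        m = np.zeros((11, 11, 11), bool)
        m[1:10, 1:10, 1:10] = True
        for k in (1, 3, 7):
            assert smooth_mask(m, k)[5, 5, 5]

    def test_isolated_voxel_removed(self):
        m = np.zeros((7, 7, 7), bool)
        m[3, 3, 3] = True               # neighbourhood sum 1 < 14
        assert not smooth_mask(m, 1).any()

    def test_cube_corner_removed(self):
        m = np.zeros((9, 9, 9), bool)
        m[2:7, 2:7, 2:7] = True
        out = smooth_mask(m, 1)
        assert not out[2, 2, 2]         # corner sees only 8 of 27
        assert out[4, 4, 4]

    def test_k_out_of_range(self):
        m = np.ones((5, 5, 5), bool)
        for k in (0, 8):
            with pytest.raises(ValueError):
                smooth_mask(m, k)

    def test_nested_on_boxes(self):
        m = np.zeros((14, 14, 14), bool)
        m[2:12, 2:9, 2:11] = True
        prev = m
        for k in range(1, 8):
            out = smooth_mask(m, k)
            assert not (out & ~prev).any()      # output(k) subset output(k-1)
            prev = out


class TestSkeletonize:
    def test_thin_line_unchanged(self):
        m = np.zeros((20, 9, 9), bool)
        m[2:18, 4, 4] = True
        out = skeletonize(m)
        assert np.array_equal(out, m)

    def test_cylinder_gives_single_axis_path(self):
        m = cylinder()
        s = skeletonize(m)
        assert s.sum() > 0
        assert (s & ~m).sum() == 0              # subset of the mask
        _, n = cc_label(s, np.ones((3, 3, 3)))
        assert n == 1
        g = extract_graph(s, distance_transform_edt(m))
        assert (g.n_nodes, g.n_edges) == (2, 1)
        ends = np.asarray([n_.position for n_ in g.nodes])
        axis_ends = np.asarray([[0, 10, 10], [39, 10, 10]])
        for e in ends:
            assert min(np.linalg.norm(e - a) for a in axis_ends) <= 3.0

    def test_two_tubes_two_components(self):
        m = cylinder(shape=(40, 30, 30))
        m2 = np.zeros_like(m)
        m2[:, :, :] = False
        zz, yy, xx = np.mgrid[:40, :30, :30]
        m2[(yy - 22) ** 2 + (xx - 22) ** 2 <= 9] = True
        both = m | m2
        _, n_in = cc_label(both, np.ones((3, 3, 3)))
        s = skeletonize(both)
        _, n_out = cc_label(s, np.ones((3, 3, 3)))
        assert n_in == n_out == 2

    def test_empty_mask_empty_skeleton(self):
        assert not skeletonize(np.zeros((5, 5, 5), bool)).any()


class TestExtractGraph:
    def test_straight_path(self):
        m = np.zeros((20, 9, 9), bool)
        m[2:18, 4, 4] = True
        g = extract_graph(m, distance_transform_edt(m))
        assert (g.n_nodes, g.n_edges) == (2, 1)
        samples = g.edges[0].samples
        assert tuple(samples[0].position) == tuple(g.nodes[g.edges[0].u].position)
        assert tuple(samples[-1].position) == tuple(g.nodes[g.edges[0].v].position)

    def test_y_shape(self):
        m = np.zeros((30, 30, 30), bool)
        m[2:13, 10, 10] = True                       # stem
        for i in range(1, 10):
            m[12 + i, 10 + i, 10] = True             # diagonal arm
            m[12 + i, 10 - i, 10] = True             # diagonal arm
        g = extract_graph(m, distance_transform_edt(m))
        assert (g.n_nodes, g.n_edges) == (4, 3)
        degrees = {}
        for e in g.edges:
            degrees[e.u] = degrees.get(e.u, 0) + 1
            degrees[e.v] = degrees.get(e.v, 0) + 1
        assert sorted(degrees.values()) == [1, 1, 1, 3]

    def test_diamond_ring_self_loop(self):
        m = np.zeros((5, 20, 20), bool)
        for i in range(-6, 7):
            j = 6 - abs(i)
            m[2, 10 + i, 10 + j] = True
            if j:
                m[2, 10 + i, 10 - j] = True
        g = extract_graph(m, distance_transform_edt(m))
        assert (g.n_nodes, g.n_edges) == (1, 1)
        assert g.edges[0].u == g.edges[0].v

    def test_sample_radii_match_distance_map_exactly(self):
        m = cylinder()
        s = skeletonize(m)
        dist = distance_transform_edt(m)
        g = extract_graph(s, dist)
        for e in g.edges:
            for p in e.samples:
                assert p.radius == dist[tuple(int(c) for c in p.position)]

    def test_edge_sample_count_invariant(self):
        m = cylinder()
        g = extract_graph(skeletonize(m), distance_transform_edt(m))
        assert sum(len(e.samples) for e in g.edges) >= 2 * g.n_edges

    def test_empty_skeleton_empty_graph(self):
        g = extract_graph(np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4)))
        assert (g.n_nodes, g.n_edges) == (0, 0)


class TestCandidateGraphs:
    def test_thin_tube_vanishes_at_computed_scale(self):
        m = cylinder(radius=2)
        # direct smoothing computation gives the vanishing scale
        alive = []
        cur = m
        for k in range(1, 8):
            cur = smooth_mask(cur, 1)
            if cur.any():
                alive.append(k)
        graphs = candidate_graphs(m)
        ks = {g.provenance_k for g in graphs}
        assert ks and ks <= set(alive)   # nothing past the vanishing scale

    def test_bridged_tubes_separate_at_larger_scale(self):
        """Two vessels joined by a thin spurious tubelet: one connected
        graph at low smoothing, disconnected graphs once smoothing
        removes the high-curvature bridge."""
        shape = (44, 34, 40)
        zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
        a = (yy - 9) ** 2 + (xx - 18) ** 2 <= 16
        b = (yy - 23) ** 2 + (xx - 18) ** 2 <= 16
        bridge = ((zz - 21) ** 2 + (xx - 18) ** 2 <= 4) & (yy >= 9) & (yy <= 23)
        m = a | b | bridge
        graphs = candidate_graphs(m)
        comp = {g.provenance_k: g.n_components() for g in graphs}
        ks = sorted(comp)
        assert comp[ks[0]] == 1                     # merged at low k
        assert any(comp[k] >= 2 for k in ks[1:])    # separated later

    def test_all_scales_empty_raises(self):
        m = np.zeros((9, 9, 9), bool)
        m[4, 4, 4] = True
        with pytest.raises(VesselPoolVanishedError):
            candidate_graphs(m)

    def test_empty_pool_raises(self):
        with pytest.raises(VesselPoolVanishedError):
            candidate_graphs(np.zeros((5, 5, 5), bool))

    def test_deduplication_keeps_smallest_k(self):
        m = np.zeros((30, 17, 17), bool)
        zz, yy, xx = np.mgrid[:30, :17, :17]
        m[(yy - 8) ** 2 + (xx - 8) ** 2 <= 36] = True   # fat stable tube
        graphs = candidate_graphs(m)
        ks = [g.provenance_k for g in graphs]
        assert ks == sorted(set(ks))
        sigs = {(g.n_nodes, g.n_edges,
                 tuple(tuple(n.position) for n in g.nodes)) for g in graphs}
        assert len(sigs) == len(graphs)
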