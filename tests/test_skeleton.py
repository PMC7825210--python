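import numpy as np
import pytest
from oracles import brute_force_neighbor_counts

from vcaseg import skeleton
from vcaseg.skeleton import FilterParams


def line_mask(length=20, shape=(5, 24), row=2, col0=2):
    m = np.zeros(shape, dtype=bool)
    m[row, col0 : col0 + length] = True
    return m


def diamond_ring(radius):
    """Closed diagonal ring: each pixel has exactly two 8-neighbors."""
    n = 2 * radius + 3
    m = np.zeros((n, n), dtype=bool)
    c = n // 2
    for dr in range(-radius, radius + 1):
        dc = radius - abs(dr)
        m[c + dr, c + dc] = m[c + dr, c - dc] = True
    return m


def y_mask():
    """Three 10-px arms meeting at one junction pixel."""
    m = np.zeros((25, 25), dtype=bool)
    m[12, 2:13] = True          # horizontal arm ending at (12, 12)
    for i in range(1, 11):
        m[12 - i, 12 + i] = True  # up-right diagonal arm
        m[12 + i, 12 + i] = True  # down-right diagonal arm
    return m


class TestSkeletonize:
    def test_empty_mask_gives_empty_skeleton(self):
        assert not skeleton.skeletonize(np.zeros((8, 8), dtype=bool)).any()

    def test_one_pixel_line_already_thin(self):
        m = line_mask()
        sk = skeleton.skeletonize(m)
        assert np.array_equal(sk, m)

    def test_filled_rectangle_thins_to_single_path(self):
        m = np.zeros((9, 26), dtype=bool)
        m[2:7, 3:23] = True  # 5 x 20 rectangle
        sk = skeleton.skeletonize(m)
        assert sk.any() and not (sk & ~m).any()
        graph = skeleton.build_graph(sk)
        assert len(graph.components) == 1
        counts = skeleton.neighbor_counts(sk)
        assert (counts[sk] <= 2).all()  # a path: no bifurcations


class TestBuildGraph:
    def test_straight_line_decomposition(self):
        graph = skeleton.build_graph(line_mask())
        assert len(graph.components) == 1
        comp = graph.components[0]
        assert comp.total_length == 20
        assert len(comp.bifurcation_points) == 0
        assert len(comp.breakpoints) == 2
        assert len(comp.branches) == 1 and comp.branches[0].length == 20

    def test_y_shape_has_one_bifurcation_three_breakpoints_three_branches(self):
        graph = skeleton.build_graph(y_mask())
        comp = graph.components[0]
        assert len(comp.bifurcation_points) == 1
        assert len(comp.breakpoints) == 3
        assert len(comp.branches) == 3
        # Branch pixels jointly cover the component.
        assert {p for b in comp.branches for p in b.pixels} == set(comp.pixels)

    def test_isolated_pixel_recorded_with_length_one(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        comp = skeleton.build_graph(m).components[0]
        assert comp.total_length == 1 and len(comp.breakpoints) == 0

    def test_closed_loop_has_no_nodes_one_cycle_branch(self):
        m = diamond_ring(radius=3)  # every ring pixel has exactly 2 neighbors
        comp = skeleton.build_graph(m).components[0]
        assert comp.n_nodes == 0 and comp.is_pure_loop
        assert len(comp.branches) == 1 and comp.branches[0].length == comp.total_length

    @pytest.mark.parametrize("seed", range(10))
    def test_classification_matches_brute_force_neighbor_counts(self, seed):
        g = np.random.default_rng(seed)
        sk = skeleton.skeletonize(g.uniform(size=(24, 24)) < 0.35)
        counts = brute_force_neighbor_counts(sk)
        graph = skeleton.build_graph(sk)
        for comp in graph.components:
            for p in comp.pixels:
                if counts[p] >= 3:
                    assert p in comp.bifurcation_points
                elif counts[p] == 1:
                    assert p in comp.breakpoints
                else:
                    assert p not in comp.bifurcation_points and p not in comp.breakpoints
        # Component pixel bookkeeping: totals add up to the skeleton size.
        assert sum(c.total_length for c in graph.components) == int(sk.sum())

    def test_non_thin_input_warns_but_builds(self):
        m = np.zeros((4, 4), dtype=bool)
        m[1:3, 1:3] = True
        with pytest.warns(UserWarning, match="unit-width"):
            graph = skeleton.build_graph(m)
        assert graph.total_pixels == 4


class TestFilterPieces:
    def test_short_line_removed_by_ratio_rule(self):
        # 5-px line: ratio 5/2 = 2.5 < 3.0 -> gone (branch length 5 is not < 5).
        graph = skeleton.build_graph(line_mask(length=5, shape=(3, 9), row=1))
        out = skeleton.filter_pieces(graph)
        assert out.total_pixels == 0

    def test_long_line_untouched(self):
        graph = skeleton.build_graph(line_mask(length=40, shape=(5, 44)))
        out = skeleton.filter_pieces(graph)
        assert out.total_pixels == 40

    def test_short_terminal_spur_pruned_from_long_vessel(self):
        m = line_mask(length=30, shape=(8, 34))
        m[3, 10] = m[4, 10] = True  # 2-px spur hanging off the line
        graph = skeleton.build_graph(m)
        out = skeleton.filter_pieces(graph, FilterParams(min_branch_length=5))
        # Tip removed; the spur pixel adjacent to the line is a junction
        # (8-connected to three line pixels) and junctions are retained.
        assert not out.skeleton[4, 10]
        assert out.total_pixels == 31

    def test_isolated_pixels_removed(self):
        m = np.zeros((10, 10), dtype=bool)
        m[1, 1] = m[8, 8] = True
        out = skeleton.filter_pieces(skeleton.build_graph(m))
        assert out.total_pixels == 0

    def test_large_pure_loop_kept(self):
        m = diamond_ring(radius=5)
        out = skeleton.filter_pieces(skeleton.build_graph(m))
        assert out.total_pixels == int(m.sum())

    def test_idempotent_and_shrinking(self, default_truth):
        from vcaseg import binarization, network

        thr = binarization.otsu_threshold(default_truth.image)
        net = network.extract_network(default_truth.image, threshold=thr)
        binary = binarization.binarize_network(default_truth.image, net, thr)
        graph = skeleton.build_graph(skeleton.skeletonize(binary))
        once = skeleton.filter_pieces(graph)
        twice = skeleton.filter_pieces(once)
        assert once.total_pixels <= graph.total_pixels
        assert np.array_equal(once.skeleton, twice.skeleton)

    def test_identity_on_clean_long_branches(self):
        m = y_mask()  # arms of 10-11 px, ratio 31/4 = 7.75
        graph = skeleton.build_graph(m)
        out = skeleton.filter_pieces(graph)
        assert np.array_equal(out.skeleton, graph.skeleton)


class TestMaskFromGraph:
    def test_all_components_survive_mask_unchanged(self):
        m = line_mask()
        graph = skeleton.filter_pieces(skeleton.build_graph(skeleton.skeletonize(m)))
        assert np.array_equal(skeleton.mask_from_graph(graph, m), m)

    def test_no_survivors_empty_mask(self):
        m = np.zeros((6, 6), dtype=bool)
        m[2, 2] = True
        graph = skeleton.filter_pieces(skeleton.build_graph(m))
        assert not skeleton.mask_from_graph(graph, m).any()

    def test_mixed_case_matches_independent_labeling(self):
        from scipy import ndimage

        m = np.zeros((12, 40), dtype=bool)
        m[2, 2:32] = True      # long line: survives
        m[8, 3:7] = True       # short fragment: removed
        graph = skeleton.filter_pieces(skeleton.build_graph(m))
        got = skeleton.mask_from_graph(graph, m)
        labels, _ = ndimage.label(m, structure=np.ones((3, 3)))
        surviving = {labels[p] for c in graph.components for p in c.pixels}
        want = np.isin(labels, sorted(surviving)) & m
        assert np.array_equal(got, want)


def test_component_table_flags_kept_and_removed():
    m = np.zeros((10, 50), dtype=bool)
    m[2, 2:42] = True  # ratio 20
    m[7, 2:7] = True   # ratio 2.5
    table = skeleton.component_table(skeleton.build_graph(m))
    assert set(table.columns) >= {"total_length_px", "n_bifurcations", "n_breakpoints", "kept"}
    assert sorted(table["kept"]) == [False, True]
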