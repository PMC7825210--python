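import numpy as np
import pytest
from oracles import bfs_closure, brute_force_starting_points

from vcaseg import network
from vcaseg.errors import ValidationError
from vcaseg.network import GrowthParams, PixelSet, StartPointParams


def random_effective_map(seed, shape=(32, 32), density=0.3):
    g = np.random.default_rng(seed)
    eff = g.uniform(size=shape) < density
    img = np.where(eff, 0.9, 0.1)
    return eff, img


class TestPixelSet:
    def test_points_round_trip_and_bounds(self):
        ps = PixelSet.from_points({(0, 0), (2, 3)}, (4, 5))
        assert ps.points == {(0, 0), (2, 3)}
        assert len(ps) == 2 and (2, 3) in ps
        with pytest.raises(Exception):
            PixelSet.from_points({(4, 0)}, (4, 5))

    def test_union_and_subset(self):
        a = PixelSet.from_points({(0, 0)}, (3, 3))
        b = PixelSet.from_points({(1, 1)}, (3, 3))
        u = a.union(b)
        assert a.issubset(u) and b.issubset(u) and len(u) == 2


class TestDetectStartingPoints:
    def test_uniform_zero_image_yields_empty_set(self):
        out = network.detect_starting_points(np.zeros((16, 16)), threshold=0.5)
        assert len(out) == 0

    def test_center_of_solid_square_is_starting_point(self):
        img = np.zeros((21, 21))
        img[:, :] = 0.9  # solid bright block: every probe line is full
        out = network.detect_starting_points(img, StartPointParams(), threshold=0.5)
        assert (10, 10) in out

    def test_isolated_pixel_is_not_a_starting_point(self):
        img = np.zeros((15, 15))
        img[7, 7] = 1.0  # all 4 probe lines empty -> proportion 1.0
        out = network.detect_starting_points(img, StartPointParams(), threshold=0.5)
        assert (7, 7) not in out

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("n_directions", [2, 4, 8])
    def test_matches_brute_force_line_scan(self, seed, n_directions):
        eff, img = random_effective_map(seed)
        params = StartPointParams(n_directions=n_directions)
        got = network.detect_starting_points(img, params, threshold=0.5).points
        want = brute_force_starting_points(eff, 7, n_directions, 0.5)
        assert got == want


class TestGrowNetwork:
    def test_empty_starts_give_empty_network(self, rng):
        img = rng.uniform(size=(16, 16))
        out = network.grow_network(img, PixelSet.empty((16, 16)), threshold=0.5)
        assert len(out) == 0

    def test_gap_within_two_pixels_is_bridged(self):
        img = np.zeros((9, 21))
        img[4, 2:9] = 0.9
        img[4, 10:19] = 0.9  # nearest pixels (4,8)-(4,10): distance exactly 2
        starts = PixelSet.from_points({(4, 2)}, img.shape)
        out = network.grow_network(img, starts, GrowthParams(d_max=2.0), threshold=0.5)
        assert (4, 18) in out  # far segment reached across the gap

    def test_gap_beyond_two_pixels_is_not_bridged(self):
        img = np.zeros((9, 21))
        img[4, 2:9] = 0.9
        img[4, 12:19] = 0.9  # nearest distance 4 > d_max
        starts = PixelSet.from_points({(4, 2)}, img.shape)
        out = network.grow_network(img, starts, GrowthParams(d_max=2.0), threshold=0.5)
        assert (4, 12) not in out

    @pytest.mark.parametrize("seed", range(25))
    def test_equals_bfs_closure_oracle(self, seed):
        eff, img = random_effective_map(seed)
        g = np.random.default_rng(seed + 1000)
        candidates = np.argwhere(eff)
        if candidates.size == 0:
            pytest.skip("empty map")
        picks = candidates[g.integers(0, len(candidates), size=3)]
        starts = {tuple(p) for p in picks}
        got = network.grow_network(
            img, PixelSet.from_points(starts, eff.shape), threshold=0.5
        ).points
        assert got == bfs_closure(eff, starts)

    def test_monotone_in_starts_and_threshold(self):
        eff, img = random_effective_map(99)
        candidates = [tuple(p) for p in np.argwhere(eff)[:6]]
        small = network.grow_network(
            img, PixelSet.from_points(candidates[:2], eff.shape), threshold=0.5
        )
        large = network.grow_network(
            img, PixelSet.from_points(candidates, eff.shape), threshold=0.5
        )
        assert small.issubset(large)
        stricter = network.grow_network(
            img, PixelSet.from_points(candidates[:2], eff.shape), threshold=0.95
        )
        assert stricter.issubset(small)

    def test_starts_always_contained_in_result(self):
        img = np.zeros((8, 8))
        starts = PixelSet.from_points({(3, 3)}, (8, 8))  # start below threshold
        out = network.grow_network(img, starts, threshold=0.5)
        assert starts.issubset(out)


class TestRotation:
    def test_zero_turns_is_identity(self, rng):
        img = rng.uniform(size=(6, 9))
        rot, rmap = network.rotate_image(img, 0)
        assert np.array_equal(rot, img)
        assert rmap.to_original(2, 5) == (2, 5)

    def test_four_quarter_turns_compose_to_identity(self, rng):
        img = rng.uniform(size=(7, 11))
        out = img
        for _ in range(4):
            out, _ = network.rotate_image(out, 1)
        assert np.array_equal(out, img)

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_impulse_tracking_confirms_coordinate_map(self, k):
        img = np.zeros((5, 8))
        img[1, 6] = 1.0
        rot, rmap = network.rotate_image(img, k)
        (r_rot, c_rot) = tuple(np.argwhere(rot == 1.0)[0])
        assert rmap.to_original(int(r_rot), int(c_rot)) == (1, 6)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_mask_map_back_inverts_rotation(self, k, rng):
        mask = rng.uniform(size=(6, 10)) > 0.5
        rot, rmap = network.rotate_image(mask, k)
        assert np.array_equal(rmap.mask_to_original(rot), mask)

    def test_non_quarter_turn_rejected(self):
        with pytest.raises(ValidationError):
            network.rotate_image(np.zeros((4, 4)), 4)


class TestExtractNetwork:
    def test_no_effective_pixels_gives_empty_set(self):
        out = network.extract_network(np.zeros((16, 16)), threshold=0.5)
        assert len(out) == 0

    def test_superset_of_unrotated_run(self, clean_truth):
        img = clean_truth.image
        sp, gp = StartPointParams(), GrowthParams()
        starts = network.detect_starting_points(img, sp)
        single = network.grow_network(img, starts, gp)
        merged = network.extract_network(img, sp, gp)
        assert single.issubset(merged)

    def test_equals_bfs_closure_of_merged_starting_points(self, clean_truth):
        img = clean_truth.image
        from vcaseg.binarization import otsu_threshold

        thr = otsu_threshold(img)
        sp = StartPointParams()
        all_starts = set()
        for k in range(4):
            rot, rmap = network.rotate_image(img, k)
            for r, c in network.detect_starting_points(rot, sp, threshold=thr).points:
                all_starts.add(rmap.to_original(r, c))
        want = bfs_closure(np.asarray(img) >= thr, all_starts)
        got = network.extract_network(img, sp, GrowthParams(), threshold=thr).points
        assert got == want

    def test_rotation_equivariance(self, default_truth):
        img = default_truth.image
        merged = network.extract_network(img)
        rot, rmap = network.rotate_image(img, 1)
        merged_rot = network.extract_network(rot)
        assert rmap.pixelset_to_original(merged_rot) == merged
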