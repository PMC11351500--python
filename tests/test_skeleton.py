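import numpy as np
import pytest
from scipy import ndimage as ndi

from veinwidth import ValidationError, make_vessel
from veinwidth.skeleton import (SkeletonMap, neighbor_count, prune_spurs,
                                skeleton_points, transition_count,
                                zhang_suen_thin)


def _thin_oracle(mask, max_iters=100):
    """Direct per-pixel translation of two-subiteration thinning.

    Independent of the vectorized implementation: explicit Python loops over
    pixels, neighbors read one by one in clockwise order from north.
    """
    a = [[int(v) for v in row] for row in mask]
    h, w = len(a), len(a[0])
    offs = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]

    def nb(i, j):
        out = []
        for di, dj in offs:
            r, c = i + di, j + dj
            out.append(a[r][c] if 0 <= r < h and 0 <= c < w else 0)
        return out

    for _ in range(max_iters):
        changed = False
        for second in (False, True):
            marked = []
            for i in range(h):
                for j in range(w):
                    if a[i][j] != 1:
                        continue
                    p2, p3, p4, p5, p6, p7, p8, p9 = nb(i, j)
                    b = p2 + p3 + p4 + p5 + p6 + p7 + p8 + p9
                    seq = [p2, p3, p4, p5, p6, p7, p8, p9, p2]
                    trans = sum(1 for x, y in zip(seq, seq[1:]) if (x, y) == (0, 1))
                    if not (2 <= b <= 6 and trans == 1):
                        continue
                    if not second:
                        if p2 * p4 * p6 == 0 and p4 * p6 * p8 == 0:
                            marked.append((i, j))
                    else:
                        if p2 * p4 * p8 == 0 and p2 * p6 * p8 == 0:
                            marked.append((i, j))
            for i, j in marked:
                a[i][j] = 0
            changed = changed or bool(marked)
        if not changed:
            break
    return np.array(a, dtype=bool)


class TestNeighborhoodCounts:
    def test_neighbor_count_extremes(self):
        assert neighbor_count([0] * 8) == 0
        assert neighbor_count([1] * 8) == 8

    def test_transition_count_alternating(self):
        assert transition_count([1, 0, 1, 0, 1, 0, 1, 0]) == 4

    def test_transition_count_single_run(self):
        assert transition_count([0, 1, 1, 1, 0, 0, 0, 0]) == 1

    def test_three_transition_neighborhood_not_deletable(self):
        # a neighborhood whose cyclic sequence changes 0->1 three times fails
        # the transition condition in both subiterations
        nb = [1, 0, 1, 0, 1, 1, 1, 0]
        assert transition_count(nb) == 3
        grid = np.zeros((3, 3), bool)
        grid[1, 1] = True
        offs = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
        for v, (dr, dc) in zip(nb, offs):
            grid[1 + dr, 1 + dc] = bool(v)
        thinned = zhang_suen_thin(grid)
        assert thinned.pixels[1, 1]

    def test_wrong_arity_raises(self):
        with pytest.raises(ValidationError):
            neighbor_count([1, 0, 1])


class TestThinning:
    def test_isolated_pixel_preserved(self):
        grid = np.zeros((7, 7), bool)
        grid[3, 3] = True
        assert np.array_equal(zhang_suen_thin(grid).pixels, grid)

    def test_one_pixel_line_unchanged(self):
        grid = np.zeros((9, 12), bool)
        grid[4, 2:10] = True
        assert np.array_equal(zhang_suen_thin(grid).pixels, grid)

    def test_solid_bar_thins_to_middle_row(self):
        grid = np.zeros((11, 24), bool)
        grid[3:8, 2:22] = True
        skel = zhang_suen_thin(grid).pixels
        rows = np.unique(np.nonzero(skel)[0])
        assert rows.tolist() == [5]
        assert np.array_equal(skel, _thin_oracle(grid))

    def test_empty_mask_raises(self):
        with pytest.raises(ValidationError):
            zhang_suen_thin(np.zeros((5, 5), bool))

    def test_matches_brute_force_oracle_on_random_masks(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            mask = ndi.binary_dilation(rng.random((32, 32)) > 0.9,
                                       iterations=rng.integers(1, 3))
            if not mask.any():
                continue
            assert np.array_equal(zhang_suen_thin(mask).pixels, _thin_oracle(mask))

    def test_idempotent(self, rng):
        mask = ndi.binary_dilation(rng.random((32, 32)) > 0.92, iterations=2)
        skel = zhang_suen_thin(mask).pixels
        assert np.array_equal(zhang_suen_thin(skel).pixels, skel)

    def test_connectivity_preserved_on_vessel_masks(self):
        eight = np.ones((3, 3), bool)
        for shape in ("straight", "sinusoidal", "bifurcating"):
            mask = make_vessel(shape, width=7).mask
            skel = zhang_suen_thin(mask).pixels
            assert ndi.label(skel, eight)[1] == ndi.label(mask, eight)[1]

    def test_one_pixel_width(self):
        # no skeleton pixel may sit inside a fully-foreground 3x3 block
        mask = make_vessel("sinusoidal", width=9).mask
        skel = zhang_suen_thin(mask).pixels
        filled = ndi.minimum_filter(skel.astype(np.uint8), size=3, mode='constant', cval=0)
        assert not filled.any()


class TestSkeletonPoints:
    def test_horizontal_line_in_column_order(self):
        grid = np.zeros((9, 12), bool)
        grid[5, 2:10] = True
        pts = skeleton_points(SkeletonMap(pixels=grid))
        assert len(pts) == 8
        assert pts in ([(5, c) for c in range(2, 10)],
                       [(5, c) for c in range(9, 1, -1)])

    def test_singleton(self):
        grid = np.zeros((5, 5), bool)
        grid[2, 2] = True
        assert skeleton_points(SkeletonMap(pixels=grid)) == [(2, 2)]

    def test_y_shape_lists_every_pixel_once(self):
        grid = np.zeros((12, 12), bool)
        grid[6, 1:9] = True
        for k in range(4):
            grid[5 - k, 8 + min(k, 3)] = True
            grid[7 + k, 8 + min(k, 3)] = True
        pts = skeleton_points(SkeletonMap(pixels=grid))
        assert len(pts) == len(set(pts)) == int(grid.sum())
        assert set(pts) == set(zip(*np.nonzero(grid)))

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            skeleton_points(SkeletonMap(pixels=np.zeros((4, 4), bool)))


def test_prune_spurs_removes_short_branch():
    grid = np.zeros((15, 20), bool)
    grid[7, 2:18] = True   # main line
    grid[6, 10] = grid[5, 10] = True  # 2-px spur
    pruned = prune_spurs(SkeletonMap(pixels=grid), min_length=3)
    assert not pruned.pixels[5, 10] and not pruned.pixels[6, 10]
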