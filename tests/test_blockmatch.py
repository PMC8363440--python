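"""Block, pyramid and search-strategy behaviour of the matching engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from bmptrack.blockmatch import (
    Block,
    Frame,
    InvalidBlockError,
    NoValidCandidateError,
    SearchWindow,
    SizeMismatchError,
    bmp_search,
    build_block_pyramid,
    global_search,
    log_search,
    sad,
    sad_at_layer,
)

int_blocks_8 = arrays(
    np.int64, (8, 8), elements=st.integers(min_value=0, max_value=255)
)


def brute_force_best(template, frame, window):
    """Independent exhaustive oracle: plain Python loops over candidates."""
    B = template.pixels.shape[0]
    h, w = frame.pixels.shape
    r0, c0 = window.center_rc
    best = None
    for dr in range(-window.radius_px, window.radius_px + 1):
        for dc in range(-window.radius_px, window.radius_px + 1):
            r, c = r0 + dr, c0 + dc
            if r < 0 or c < 0 or r + B > h or c + B > w:
                continue
            s = float(np.sum(np.abs(frame.pixels[r : r + B, c : c + B] - template.pixels)))
            if best is None or s < best[0]:
                best = (s, (dr, dc))
    return best


class TestSad:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (np.arange(16.0).reshape(4, 4), np.arange(16.0).reshape(4, 4), 0.0),
            ([[5.0]], [[3.0]], 2.0),
            ([[1, 2], [3, 4]], [[4, 3], [2, 1]], 8.0),
        ],
    )
    def test_values(self, a, b, expected):
        assert sad(Block(np.asarray(a, float)), Block(np.asarray(b, float))) == expected

    def test_size_mismatch(self):
        with pytest.raises(SizeMismatchError):
            sad(Block(np.zeros((2, 2))), Block(np.zeros((4, 4))))

    def test_zero_iff_identical(self, rng):
        a = rng.integers(0, 9, (4, 4)).astype(float)
        b = a.copy()
        b[0, 0] += 1
        assert sad(Block(a), Block(a)) == 0
        assert sad(Block(a), Block(b)) > 0


class TestPyramid:
    def test_two_by_two(self):
        p = build_block_pyramid(Block(np.array([[1.0, 2.0], [3.0, 4.0]])))
        assert p.depth == 1
        np.testing.assert_array_equal(p.layers[0], [[10.0]])
        np.testing.assert_array_equal(p.layers[1], [[1, 2], [3, 4]])

    def test_constant_block(self):
        p = build_block_pyramid(Block(np.ones((4, 4))))
        np.testing.assert_array_equal(p.layers[0], [[16.0]])
        np.testing.assert_array_equal(p.layers[1], 4 * np.ones((2, 2)))
        np.testing.assert_array_equal(p.layers[2], np.ones((4, 4)))

    def test_sum_pool_oracle(self, rng):
        b = rng.integers(0, 256, (8, 8)).astype(float)
        p = build_block_pyramid(Block(b))
        for lv in range(1, p.depth + 1):
            fine, coarse = p.layers[lv], p.layers[lv - 1]
            for i in range(coarse.shape[0]):
                for j in range(coarse.shape[1]):
                    assert coarse[i, j] == fine[2 * i : 2 * i + 2, 2 * j : 2 * j + 2].sum()

    def test_non_power_of_two_rejected(self):
        with pytest.raises(InvalidBlockError):
            Block(np.zeros((3, 3)))

    def test_block_must_fit_frame(self):
        with pytest.raises(InvalidBlockError):
            Block.from_frame(Frame(np.zeros((8, 8))), (6, 0), 4)


class TestSadAtLayer:
    def test_hand_example(self):
        pa = build_block_pyramid(Block(np.array([[1.0, 2.0], [3.0, 4.0]])))
        pb = build_block_pyramid(Block(np.array([[4.0, 3.0], [2.0, 1.0]])))
        assert sad_at_layer(pa, pb, 1) == 8.0
        assert sad_at_layer(pa, pb, 0) == 0.0

    def test_identical_zero_everywhere(self, rng):
        p = build_block_pyramid(Block(rng.random((8, 8))))
        assert all(sad_at_layer(p, p, lv) == 0 for lv in range(p.depth + 1))

    def test_depth_mismatch(self):
        pa = build_block_pyramid(Block(np.zeros((2, 2))))
        pb = build_block_pyramid(Block(np.zeros((4, 4))))
        with pytest.raises(SizeMismatchError):
            sad_at_layer(pa, pb, 0)

    @settings(max_examples=100, derandomize=True)
    @given(a=int_blocks_8, b=int_blocks_8)
    def test_monotone_in_layer(self, a, b):
        """Coarse SAD lower-bounds fine SAD (exact on integers)."""
        pa = build_block_pyramid(Block(a.astype(float)))
        pb = build_block_pyramid(Block(b.astype(float)))
        sads = [sad_at_layer(pa, pb, lv) for lv in range(pa.depth + 1)]
        assert all(s0 <= s1 for s0, s1 in zip(sads, sads[1:]))
        # finest layer agrees with direct summation
        assert sads[-1] == np.abs(a - b).sum()


def _random_instance(rng, frame_side=32, block_side=8, radius=5):
    f = Frame(rng.integers(0, 256, (frame_side, frame_side)).astype(float))
    margin = frame_side - block_side
    center = (int(rng.integers(0, margin + 1)), int(rng.integers(0, margin + 1)))
    tpl = Block(rng.integers(0, 256, (block_side, block_side)).astype(float))
    return tpl, f, SearchWindow(center, radius)


class TestGlobalSearch:
    def test_exact_copy_recovery(self, rng):
        f = np.zeros((32, 32))
        t = rng.random((8, 8)) + 0.5
        f[12:20, 15:23] = t
        res = global_search(Block(t), Frame(f), SearchWindow((10, 12), 4))
        assert res.displacement_rc == (2, 3)
        assert res.sad == 0.0
        assert res.n_pruned == 0

    def test_tie_break_constant_frame(self):
        res = global_search(
            Block(np.ones((4, 4))), Frame(np.ones((16, 16))), SearchWindow((6, 6), 1)
        )
        assert res.displacement_rc == (-1, -1)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            tpl, f, w = _random_instance(rng)
            res = global_search(tpl, f, w)
            s, d = brute_force_best(tpl, f, w)
            assert (res.displacement_rc, res.sad) == (d, s)

    def test_candidate_count_bound(self, rng):
        tpl, f, w = _random_instance(rng, radius=3)
        res = global_search(tpl, f, w)
        assert res.n_candidates_evaluated <= (2 * w.radius_px + 1) ** 2

    def test_no_valid_candidate(self):
        f = Frame(np.zeros((8, 8)))
        with pytest.raises(NoValidCandidateError):
            global_search(Block(np.zeros((8, 8))), f, SearchWindow((20, 20), 1))


class TestBmpSearch:
    def test_identical_to_global(self, rng):
        for _ in range(60):
            tpl, f, w = _random_instance(rng, radius=int(rng.integers(0, 7)))
            g = global_search(tpl, f, w)
            b = bmp_search(tpl, f, w)
            assert (b.displacement_rc, b.sad) == (g.displacement_rc, g.sad)
            assert 0 <= b.n_pruned <= b.n_candidates_evaluated

    def test_prunes_on_exact_copy(self, rng):
        f = np.zeros((32, 32))
        t = rng.random((8, 8)) + 0.5
        f[12:20, 15:23] = t
        res = bmp_search(Block(t), Frame(f), SearchWindow((10, 12), 4))
        assert res.sad == 0.0
        assert res.n_pruned >= 1

    def test_degenerate_window(self, rng):
        tpl, f, _ = _random_instance(rng)
        res = bmp_search(tpl, f, SearchWindow((10, 10), 0))
        assert res.displacement_rc == (0, 0)
        assert res.n_pruned == 0


class TestLogSearch:
    def test_exact_copy_matches_global(self, rng):
        f = np.zeros((32, 32))
        t = rng.random((8, 8)) + 0.5
        f[12:20, 15:23] = t
        g = global_search(Block(t), Frame(f), SearchWindow((10, 12), 4))
        l = log_search(Block(t), Frame(f), SearchWindow((10, 12), 4))
        assert (l.displacement_rc, l.sad) == (g.displacement_rc, g.sad)

    def test_radius_one_is_exhaustive(self, rng):
        for _ in range(30):
            tpl, f, w = _random_instance(rng, radius=1)
            g = global_search(tpl, f, w)
            l = log_search(tpl, f, w)
            assert (l.displacement_rc, l.sad) == (g.displacement_rc, g.sad)

    def test_cheaper_than_global_for_wide_windows(self, rng):
        for radius in range(2, 9):
            tpl, f, w = _random_instance(rng, frame_side=48, radius=radius)
            g = global_search(tpl, f, w)
            l = log_search(tpl, f, w)
            assert l.n_candidates_evaluated < g.n_candidates_evaluated
            assert l.sad >= g.sad  # may be a local minimum, never better

    def test_determinism(self, rng):
        tpl, f, w = _random_instance(rng)
        assert log_search(tpl, f, w) == log_search(tpl, f, w)


def test_translation_equivariance(rng):
    """Shifting content and window centre together leaves the match unchanged."""
    base = rng.random((40, 40))
    tpl = Block(base[10:18, 10:18].copy())
    shift = (3, 2)
    shifted = np.roll(np.roll(base, shift[0], axis=0), shift[1], axis=1)
    for search in (global_search, bmp_search, log_search):
        r1 = search(tpl, Frame(base), SearchWindow((12, 11), 3))
        r2 = search(tpl, Frame(shifted), SearchWindow((12 + shift[0], 11 + shift[1]), 3))
        assert r1.displacement_rc == r2.displacement_rc
        assert r1.sad == pytest.approx(r2.sad)
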