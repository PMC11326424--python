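"""Dice, HD95, failure criteria, and metric invariances."""

import numpy as np
import pytest

from daugs.core import BLOODPOOL, LabelMask, MYOCARDIUM
from daugs.evaluate import detect_failure, dice, hd95
from daugs.phantom import make_phantom, internal_sampler, make_dataset

from conftest import clean_phantom_config


def ring_mask(size=40, r_in=8, r_out=14, center=None):
    c = (size - 1) / 2.0 if center is None else center
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    r = np.hypot(rr - c, cc - c)
    labels = np.zeros((size, size), dtype=int)
    labels[r < r_out] = MYOCARDIUM
    labels[r < r_in] = BLOODPOOL
    return LabelMask(labels)


class TestDice:
    def test_perfect_and_disjoint(self):
        m = ring_mask()
        assert dice(m, m, MYOCARDIUM) == 1.0
        a = np.zeros((10, 10), dtype=int)
        b = np.zeros((10, 10), dtype=int)
        a[:2, :2] = 1
        b[5:, 5:] = 1
        assert dice(LabelMask(a), LabelMask(b), MYOCARDIUM) == 0.0

    def test_direct_formula(self):
        a = np.zeros((20, 20), dtype=int)
        b = np.zeros((20, 20), dtype=int)
        a.ravel()[:100] = 1
        b.ravel()[20:120] = 1  # |A|=|B|=100, overlap 80
        assert dice(LabelMask(a), LabelMask(b), MYOCARDIUM) == pytest.approx(0.8)

    def test_empty_set_conventions(self):
        empty = LabelMask(np.zeros((5, 5), dtype=int))
        one = LabelMask(np.eye(5, dtype=int))
        assert dice(empty, empty, MYOCARDIUM) == 1.0
        assert dice(one, empty, MYOCARDIUM) == 0.0

    def test_symmetry(self, rng):
        a = LabelMask(rng.integers(0, 3, (16, 16)))
        b = LabelMask(rng.integers(0, 3, (16, 16)))
        assert dice(a, b, MYOCARDIUM) == dice(b, a, MYOCARDIUM)

    def test_unknown_class_rejected(self):
        m = ring_mask()
        with pytest.raises(ValueError):
            dice(m, m, 7)


class TestHd95:
    def test_identical_masks_zero(self):
        m = ring_mask()
        assert hd95(m, m, MYOCARDIUM) == 0.0

    def test_single_pixel_pair_distance(self):
        a = np.zeros((6, 6), dtype=int)
        b = np.zeros((6, 6), dtype=int)
        a[0, 0] = 1
        b[0, 3] = 1
        assert hd95(LabelMask(a), LabelMask(b), MYOCARDIUM) == pytest.approx(3.0)

    def test_spacing_scales_distances(self):
        a = np.zeros((6, 6), dtype=int)
        b = np.zeros((6, 6), dtype=int)
        a[0, 0] = 1
        b[0, 3] = 1
        got = hd95(LabelMask(a), LabelMask(b), MYOCARDIUM, spacing_mm=(2.0, 2.0))
        assert got == pytest.approx(6.0)

    def test_empty_side_is_infinite_with_warning(self):
        m = ring_mask()
        empty = LabelMask(np.zeros(m.shape, dtype=int))
        with pytest.warns(UserWarning):
            assert hd95(m, empty, MYOCARDIUM) == float("inf")

    def test_symmetry_and_translation_invariance(self):
        a = ring_mask(center=18.0)
        b = ring_mask(center=21.0)
        assert hd95(a, b, MYOCARDIUM) == hd95(b, a, MYOCARDIUM)
        # common translation (away from borders) leaves the distance alone
        shift = lambda m, d: LabelMask(np.roll(m.labels, d, axis=0))
        assert hd95(shift(a, 2), shift(b, 2), MYOCARDIUM) == pytest.approx(
            hd95(a, b, MYOCARDIUM)
        )

    def test_matches_brute_force(self, rng):
        def brute(a, b):
            def boundary(m):
                pts = []
                for r, c in np.argwhere(m):
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if not (0 <= rr < m.shape[0] and 0 <= cc < m.shape[1]) \
                                or not m[rr, cc]:
                            pts.append((r, c))
                            break
                return np.array(pts, float)

            pa, pb = boundary(a), boundary(b)
            d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
            return max(np.percentile(d.min(axis=1), 95),
                       np.percentile(d.min(axis=0), 95))

        n_checked = 0
        while n_checked < 100:
            a = rng.random((12, 12)) < 0.3
            b = rng.random((12, 12)) < 0.3
            if not (a.any() and b.any()):
                continue
            n_checked += 1
            got = hd95(LabelMask(a.astype(int)), LabelMask(b.astype(int)),
                       MYOCARDIUM)
            assert got == pytest.approx(brute(a, b), abs=1e-9)


class TestDetectFailure:
    def test_perfect_ring_passes(self):
        assert detect_failure(ring_mask()) == (False, False)

    def test_ring_with_gap_is_noncontiguous(self):
        m = ring_mask().labels.copy()
        c = (m.shape[0] - 1) / 2.0
        rr, cc = np.mgrid[0 : m.shape[0], 0 : m.shape[1]].astype(float)
        theta = np.arctan2(rr - c, cc - c)
        gap = (np.abs(theta) < 0.25) & (m == MYOCARDIUM)
        m[gap] = 0
        fb, fn = detect_failure(LabelMask(m))
        assert (fb, fn) == (False, True)

    def test_bloodpool_blob_inside_band_flags_inclusion(self):
        m = ring_mask(size=40, r_in=6, r_out=16).labels.copy()
        # carve a background pocket in the band and fill it with bloodpool
        m[8:12, 18:22] = BLOODPOOL
        fb, fn = detect_failure(LabelMask(m))
        assert fb is True

    def test_empty_prediction_raises_both_flags(self):
        with pytest.warns(UserWarning):
            fb, fn = detect_failure(LabelMask(np.zeros((10, 10), dtype=int)))
        assert (fb, fn) == (True, True)

    def test_speckle_below_threshold_ignored(self):
        m = ring_mask().labels.copy()
        m[1, 1] = MYOCARDIUM  # 1-px satellite
        assert detect_failure(LabelMask(m)) == (False, False)

    def test_ground_truth_phantom_masks_never_fail(self):
        for series, mask in make_dataset(10, internal_sampler("desk"), 77):
            assert detect_failure(mask) == (False, False)
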