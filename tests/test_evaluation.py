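"""Pixel-metric correctness against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tubuleseg.evaluation import MetricsReport, aggregate, binarize, overlay, score


def oracle_counts(pred, truth):
    """Nested-loop confusion counting, independent of the vectorised path."""
    tp = fp = tn = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = bool(pred[i, j]), bool(truth[i, j])
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


class TestBinarize:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0.2, 0.4, 0.6, 0.8], [0, 0, 1, 1]),
            ([0.5, 0.5], [1, 1]),  # >= convention at the boundary
            ([0.0, 0.0], [0, 0]),
        ],
    )
    def test_threshold_convention(self, values, expected):
        assert binarize(np.array(values)).tolist() == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            binarize(np.array([1.5]))


class TestScore:
    def test_perfect_overlap(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[2:5, 2:5] = 1
        r = score(m, m)
        assert (r.dsc, r.recall, r.specificity, r.fpr) == (1.0, 100.0, 100.0, 0.0)

    def test_shifted_block_example(self):
        """2x2 block shifted by (1,1) on a 4x4 grid, worked out by enumeration."""
        truth = np.zeros((4, 4), dtype=np.uint8)
        truth[0:2, 0:2] = 1
        pred = np.zeros((4, 4), dtype=np.uint8)
        pred[1:3, 1:3] = 1
        assert oracle_counts(pred, truth) == (1, 3, 9, 3)
        r = score(pred, truth)
        assert (r.tp, r.fp, r.tn, r.fn) == (1, 3, 9, 3)
        assert r.dsc == pytest.approx(0.25)
        assert r.recall == pytest.approx(25.0)
        assert r.specificity == pytest.approx(75.0)
        assert r.fpr == pytest.approx(25.0)

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        a[0, 0] = 1
        b = np.zeros((4, 4), dtype=np.uint8)
        b[3, 3] = 1
        r = score(a, b)
        assert r.dsc == 0.0 and r.recall == 0.0

    def test_empty_vs_empty_dsc_is_one(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        assert score(z, z).dsc == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            score(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_matches_bruteforce_oracle_on_random_pairs(self, rng):
        for _ in range(50):
            pred = rng.integers(0, 2, (16, 16), dtype=np.uint8)
            truth = rng.integers(0, 2, (16, 16), dtype=np.uint8)
            r = score(pred, truth)
            assert (r.tp, r.fp, r.tn, r.fn) == oracle_counts(pred, truth)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_dsc_symmetry_and_role_swap(self, seed):
        g = np.random.default_rng(seed)
        a = g.integers(0, 2, (8, 8), dtype=np.uint8)
        b = g.integers(0, 2, (8, 8), dtype=np.uint8)
        r_ab, r_ba = score(a, b), score(b, a)
        assert r_ab.dsc == pytest.approx(r_ba.dsc)
        assert (r_ab.fp, r_ab.fn) == (r_ba.fn, r_ba.fp)


class TestAggregate:
    def _rep(self, tp, fp, tn, fn):
        return MetricsReport.from_counts(tp, fp, tn, fn)

    def test_single_report_is_identity(self):
        r = self._rep(3, 1, 10, 2)
        for mode in ("macro", "micro"):
            agg = aggregate([r], mode)
            assert agg.dsc == pytest.approx(r.dsc)
            assert agg.recall == pytest.approx(r.recall)

    def test_identical_reports_agree_across_modes(self):
        r = self._rep(5, 2, 7, 2)
        assert aggregate([r, r], "macro").dsc == pytest.approx(aggregate([r, r], "micro").dsc)

    def test_macro_is_unweighted_mean(self):
        r1 = self._rep(1, 3, 9, 3)  # dsc 0.25
        r2 = self._rep(3, 1, 9, 3)  # dsc 2*3/(6+1+3)=0.6
        assert aggregate([r1, r2], "macro").dsc == pytest.approx((0.25 + 0.6) / 2)

    def test_micro_over_partition_equals_whole_image(self, rng):
        pred = rng.integers(0, 2, (16, 16), dtype=np.uint8)
        truth = rng.integers(0, 2, (16, 16), dtype=np.uint8)
        whole = score(pred, truth)
        parts = [
            score(pred[:8], truth[:8]),
            score(pred[8:], truth[8:]),
        ]
        agg = aggregate(parts, "micro")
        assert (agg.tp, agg.fp, agg.tn, agg.fn) == (whole.tp, whole.fp, whole.tn, whole.fn)
        assert agg.dsc == pytest.approx(whole.dsc)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate([], "macro")


class TestOverlay:
    def test_exact_prediction_has_no_red_or_blue(self, rng):
        truth = rng.integers(0, 2, (8, 8), dtype=np.uint8)
        img = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        out = overlay(truth, truth, img, alpha=1.0)
        assert not np.any(np.all(out == (255, 0, 0), axis=-1))
        assert not np.any(np.all(out == (0, 80, 255), axis=-1))

    def test_missed_truth_is_blue_only(self):
        truth = np.ones((4, 4), dtype=np.uint8)
        pred = np.zeros_like(truth)
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        out = overlay(pred, truth, img, alpha=1.0)
        assert np.all(out.reshape(-1, 3) == (0, 80, 255))

    def test_green_pixel_count_equals_tp(self, rng):
        pred = rng.integers(0, 2, (16, 16), dtype=np.uint8)
        truth = rng.integers(0, 2, (16, 16), dtype=np.uint8)
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        out = overlay(pred, truth, img, alpha=1.0)
        green = np.all(out == (0, 200, 0), axis=-1).sum()
        assert green == score(pred, truth).tp
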