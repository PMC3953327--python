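"""Metric suite: pixel, Rand and warping measures plus macro averages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from itertools import combinations
from scipy import ndimage

from sarsamend.metrics import (
    ConfusionCounts,
    MetricReport,
    confusion_counts,
    evaluate_maps,
    is_simple_point,
    macro_metrics,
    pixel_error,
    precision_recall_f,
    rand_error,
    rand_index,
    regions_from_boundary,
    warp_reference,
    warping_error,
)
from conftest import make_ring


def brute_force_rand(x, y):
    """O(n^2) pair enumeration oracle for the Rand index."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    keep = (x != 0) & (y != 0)
    xv, yv = x[keep], y[keep]
    agree = total = 0
    for i, j in combinations(range(xv.size), 2):
        total += 1
        if (xv[i] == xv[j]) == (yv[i] == yv[j]):
            agree += 1
    return agree / total


class TestConfusionCounts:
    def test_identity_case(self):
        m = np.zeros((5, 5), dtype=bool)
        m[1, 1] = m[2, 3] = m[4, 0] = True
        c = confusion_counts(m, m)
        assert (c.tp, c.fp, c.fn) == (3, 0, 0)
        assert c.total == 25

    def test_empty_prediction(self):
        truth = np.eye(4, dtype=bool)
        c = confusion_counts(np.zeros((4, 4)), truth)
        assert (c.tp, c.fn, c.fp) == (0, 4, 0)

    def test_fixed_3x3_pair(self):
        pred = np.zeros((3, 3), dtype=bool)
        truth = np.zeros((3, 3), dtype=bool)
        pred[0, 0] = pred[1, 1] = True
        truth[1, 1] = truth[2, 2] = True
        c = confusion_counts(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 6)

    def test_swap_exchanges_fp_fn(self):
        rng = np.random.default_rng(0)
        a = rng.random((8, 8)) < 0.3
        b = rng.random((8, 8)) < 0.3
        cab, cba = confusion_counts(a, b), confusion_counts(b, a)
        assert (cab.fp, cab.fn) == (cba.fn, cba.fp)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((3, 3)), np.zeros((4, 4)))


class TestPrecisionRecallF:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [
            (1, 1, 1, (0.5, 0.5, 0.5)),
            (8, 2, 4, (0.8, 8 / 12, 0.727272727)),
            (5, 0, 0, (1.0, 1.0, 1.0)),
        ],
    )
    def test_values(self, tp, fp, fn, expected):
        p, r, f = precision_recall_f(ConfusionCounts(tp, fp, fn, 0))
        assert (p, r, f) == pytest.approx(expected)

    def test_harmonic_mean_fixed_point(self):
        # P == R == p forces F == p
        p, r, f = precision_recall_f(ConfusionCounts(3, 1, 1, 0))
        assert p == r == f == 0.75

    def test_zero_denominators_yield_zero(self):
        p, r, f = precision_recall_f(ConfusionCounts(0, 0, 0, 9))
        assert (p, r, f) == (0.0, 0.0, 0.0)


class TestPixelError:
    def test_perfect_prediction(self):
        m = make_ring((9, 9), (4, 4), 3)
        assert pixel_error(m.astype(float), m) == 0.0

    def test_binary_equals_one_minus_f(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pred = rng.random((10, 10)) < 0.25
            truth = rng.random((10, 10)) < 0.25
            _, _, f = precision_recall_f(confusion_counts(pred, truth))
            assert pixel_error(pred.astype(float), truth) == pytest.approx(1 - f)

    def test_graded_threshold_sweep(self):
        pred = np.array([[0.9, 0.6, 0.2, 0.1]])
        truth = np.array([[1, 1, 0, 0]])
        assert pixel_error(pred, truth) == pytest.approx(0.0)


class TestRegionsFromBoundary:
    def test_all_zero_map_single_region(self):
        labels = regions_from_boundary(np.zeros((6, 7)))
        assert labels.max() == 1 and (labels == 1).all()

    def test_horizontal_line_splits_in_two(self):
        m = np.zeros((7, 7), dtype=bool)
        m[3, :] = True
        labels = regions_from_boundary(m)
        assert labels.max() == 2
        assert (labels[m] == 0).all()

    def test_closed_3x3_ring(self):
        m = np.zeros((5, 5), dtype=bool)
        m[1:4, 1:4] = True
        m[2, 2] = False
        labels = regions_from_boundary(m)
        assert labels.max() == 2
        counts = np.bincount(labels.ravel())
        assert sorted(counts[1:]) == [1, 16]
        assert counts[0] == 8


class TestRandIndex:
    def test_identity(self):
        labels = regions_from_boundary(make_ring((9, 9), (4, 4), 3))
        assert rand_index(labels, labels) == 1.0
        assert rand_error(labels, labels) == 0.0

    def test_four_pixel_example(self):
        x = np.array([[1, 1, 1, 1]])
        y = np.array([[1, 1, 2, 2]])
        assert rand_index(x, y) == pytest.approx(1 / 3)
        assert rand_error(x, y) == pytest.approx(2 / 3)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            shape = (rng.integers(2, 6), rng.integers(2, 6))
            x = rng.integers(0, 4, shape)
            y = rng.integers(0, 4, shape)
            if ((x != 0) & (y != 0)).sum() < 2:
                continue
            assert rand_index(x, y) == pytest.approx(brute_force_rand(x, y))

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        x = rng.integers(1, 4, (5, 5))
        y = rng.integers(1, 4, (5, 5))
        assert rand_error(x, y) == rand_error(y, x)

    def test_too_few_scored_pixels_raises(self):
        with pytest.raises(ValueError):
            rand_index(np.array([[0, 0]]), np.array([[0, 1]]))


class TestWarpingError:
    def test_identity_is_zero(self, ring_map):
        assert warping_error(ring_map, ring_map) == 0.0

    def test_shifted_ring_warps_to_zero(self):
        ref = make_ring((20, 20), (10, 10), 6)
        cand = make_ring((20, 20), (11, 10), 6)
        assert warping_error(cand, ref) == 0.0

    def test_split_ring_cannot_be_warped_away(self):
        ref = make_ring((32, 32), (16, 16), 9)
        cand = make_ring((32, 32), (10, 10), 5) | make_ring((32, 32), (22, 22), 5)
        assert warping_error(cand, ref) > 0.0

    def test_bounded_by_hamming_and_topology_preserved(self):
        rng = np.random.default_rng(5)
        s8 = np.ones((3, 3))
        for _ in range(15):
            ref = ndimage.binary_closing(rng.random((24, 24)) < 0.35)
            cand = ndimage.binary_closing(rng.random((24, 24)) < 0.35)
            ham = np.count_nonzero(ref != cand) / ref.size
            assert warping_error(cand, ref) <= ham + 1e-12
            warped = warp_reference(cand, ref)
            assert ndimage.label(warped, structure=s8)[1] == ndimage.label(ref, structure=s8)[1]
            assert ndimage.label(~warped)[1] == ndimage.label(~ref)[1]

    def test_simple_point_detection(self):
        img = np.zeros((3, 3), dtype=bool)
        img[1, 1] = img[1, 2] = True
        assert is_simple_point(img, 1, 1)  # end of a 2-px segment
        lone = np.zeros((3, 3), dtype=bool)
        lone[1, 1] = True
        assert not is_simple_point(lone, 1, 1)  # deleting the last pixel of a component


class TestMacroMetrics:
    def _report(self, **kw):
        base = dict(precision=1, recall=1, f_score=1, pixel_error=0,
                    rand_index=1, rand_error=0, warping_error=0)
        base.update(kw)
        return MetricReport(**base)

    def test_single_report_passthrough(self):
        r = self._report(rand_error=0.25)
        m = macro_metrics([r])
        assert m.macro_rand_error == 0.25 and m.n_images == 1

    def test_mean_of_two(self):
        m = macro_metrics([self._report(rand_error=0.2), self._report(rand_error=0.4)])
        assert m.macro_rand_error == pytest.approx(0.3)

    def test_many_reports_match_independent_mean(self):
        rng = np.random.default_rng(13)
        vals = rng.random((30, 7))
        reports = [MetricReport(*row) for row in vals]
        m = macro_metrics(reports)
        # independent mean in a second summation order
        assert m.macro_precision == pytest.approx(sum(sorted(vals[:, 0])) / 30)
        assert m.macro_warping_error == pytest.approx(sum(sorted(vals[:, 6])) / 30)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            macro_metrics([])


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_all_metrics_in_unit_interval(seed):
    """Every metric of a random binary pair lies in [0, 1]."""
    rng = np.random.default_rng(seed)
    pred = ndimage.binary_dilation(rng.random((12, 12)) < 0.1)
    truth = ndimage.binary_dilation(rng.random((12, 12)) < 0.1)
    rep = evaluate_maps(pred, truth)
    for name in ("precision", "recall", "f_score", "pixel_error",
                 "rand_index", "rand_error", "warping_error"):
        v = getattr(rep, name)
        assert 0.0 <= v <= 1.0
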