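"""The seven-metric evaluation suite against independent exhaustive oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcaunet import metrics
from mcaunet.metrics import (
    ConfusionCounts,
    EmptyMaskError,
    EmptyTruthError,
    MetricReport,
    aggregate,
    binarize,
    confusion,
    evaluate_case,
    hausdorff,
    overlap_metrics,
)

# ---------------------------------------------------------------------------
# independent oracles: exhaustive per-pixel set arithmetic and all-pairs loops
# ---------------------------------------------------------------------------


def oracle_confusion(p, g):
    tp = fp = fn = tn = 0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] and g[i, j]:
                tp += 1
            elif p[i, j]:
                fp += 1
            elif g[i, j]:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def oracle_hausdorff(p, g):
    a = [(i, j) for i in range(p.shape[0]) for j in range(p.shape[1]) if p[i, j]]
    b = [(i, j) for i in range(g.shape[0]) for j in range(g.shape[1]) if g[i, j]]
    d_ab = max(min(math.dist(x, y) for y in b) for x in a)
    d_ba = max(min(math.dist(x, y) for y in a) for x in b)
    return max(d_ab, d_ba)


def _random_pair(rng, shape=(16, 16), p_fg=0.15):
    return (
        (rng.random(shape) < p_fg).astype(np.uint8),
        (rng.random(shape) < p_fg).astype(np.uint8),
    )


class TestBinarize:
    def test_threshold_boundary_is_foreground(self):
        assert binarize(np.array([[0.5]]), 0.5) == 1

    def test_values(self):
        out = binarize(np.array([[0.4, 0.6]]), 0.5)
        assert out.tolist() == [[0, 1]]

    def test_all_below_gives_empty(self):
        assert binarize(np.full((4, 4), 0.2), 0.5).sum() == 0


class TestConfusion:
    def test_identical_masks(self, rng):
        g = (rng.random((8, 8)) < 0.3).astype(np.uint8)
        c = confusion(g, g)
        assert (c.tp, c.fp, c.fn) == (int(g.sum()), 0, 0)
        assert c.total == 64

    def test_disjoint_masks(self):
        p = np.zeros((4, 4), dtype=np.uint8)
        g = np.zeros((4, 4), dtype=np.uint8)
        p[0, :2] = 1
        g[3, :3] = 1
        c = confusion(p, g)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 2, 3, 11)

    def test_matches_exhaustive_tally(self, rng):
        for _ in range(20):
            p, g = _random_pair(rng, shape=(4, 4), p_fg=0.4)
            c = confusion(p, g)
            assert (c.tp, c.fp, c.fn, c.tn) == oracle_confusion(p, g)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2)), np.zeros((2, 3)))


class TestOverlapMetrics:
    def test_hand_arithmetic_tp1_fp1_fn1(self):
        dsc, jsc, ppv, se, rvd, voe = overlap_metrics(ConfusionCounts(1, 1, 1, 13))
        assert dsc == pytest.approx(0.5)
        assert jsc == pytest.approx(1 / 3)
        assert ppv == pytest.approx(0.5)
        assert se == pytest.approx(0.5)
        assert rvd == pytest.approx(0.0)
        assert voe == pytest.approx(2 / 3)

    def test_perfect_prediction(self):
        dsc, jsc, ppv, se, rvd, voe = overlap_metrics(ConfusionCounts(9, 0, 0, 55))
        assert (dsc, jsc, ppv, se) == (1.0, 1.0, 1.0, 1.0)
        assert (rvd, voe) == (0.0, 0.0)

    def test_double_area_covering_prediction(self):
        # pred covers truth entirely but is twice its area
        dsc, jsc, ppv, se, rvd, voe = overlap_metrics(ConfusionCounts(5, 5, 0, 54))
        assert rvd == pytest.approx(1.0)
        assert se == pytest.approx(1.0)
        assert ppv == pytest.approx(0.5)

    def test_signed_rvd(self):
        assert overlap_metrics(ConfusionCounts(2, 0, 2, 60), signed_rvd=True)[
            4
        ] == pytest.approx(-0.5)

    def test_empty_truth_raises(self):
        with pytest.raises(EmptyTruthError):
            overlap_metrics(ConfusionCounts(0, 3, 0, 61))

    @settings(derandomize=True, max_examples=200)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50)
    )
    def test_algebraic_identities(self, tp, fp, fn):
        """dsc = 2*jsc/(1+jsc) and voe = 1 - jsc on arbitrary counts."""
        if tp + fn == 0:
            return
        dsc, jsc, _, _, _, voe = overlap_metrics(ConfusionCounts(tp, fp, fn, 10))
        assert dsc == pytest.approx(2 * jsc / (1 + jsc), abs=1e-12)
        assert voe == pytest.approx(1 - jsc, abs=1e-12)


class TestHausdorff:
    def test_identical_masks_zero(self, rng):
        g = (rng.random((10, 10)) < 0.3).astype(np.uint8)
        g[5, 5] = 1
        assert hausdorff(g, g) == 0.0

    def test_three_four_five_triangle(self):
        p = np.zeros((8, 8), dtype=np.uint8)
        g = np.zeros((8, 8), dtype=np.uint8)
        p[0, 0] = 1
        g[3, 4] = 1
        assert hausdorff(p, g) == pytest.approx(5.0)

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(25):
            p, g = _random_pair(rng, shape=(12, 12), p_fg=0.1)
            if p.sum() == 0 or g.sum() == 0:
                continue
            assert hausdorff(p, g) == pytest.approx(
                oracle_hausdorff(p, g), abs=1e-12
            )

    def test_symmetry_and_triangle_inequality(self, rng):
        masks = []
        while len(masks) < 3:
            m = (rng.random((10, 10)) < 0.15).astype(np.uint8)
            if m.sum():
                masks.append(m)
        a, b, c = masks
        assert hausdorff(a, b) == pytest.approx(hausdorff(b, a))
        assert hausdorff(a, c) <= hausdorff(a, b) + hausdorff(b, c) + 1e-12

    def test_percentile_variant_bounded_by_max(self, rng):
        p, g = _random_pair(rng, shape=(16, 16), p_fg=0.2)
        assert hausdorff(p, g, percentile=95) <= hausdorff(p, g) + 1e-12

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            hausdorff(np.zeros((4, 4)), np.ones((4, 4)))


class TestEvaluateCase:
    def test_perfect_prediction(self, rng):
        g = (rng.random((12, 12)) < 0.2).astype(np.uint8)
        g[6, 6] = 1
        r = evaluate_case(g.astype(float), g)
        assert (r.dsc, r.jsc, r.ppv, r.se) == (1.0, 1.0, 1.0, 1.0)
        assert (r.hd, r.rvd, r.voe) == (0.0, 0.0, 0.0)

    def test_empty_prediction_policy(self):
        g = np.zeros((9, 13), dtype=np.uint8)
        g[4, 6] = 1
        r = evaluate_case(np.zeros((9, 13)), g)
        assert (r.dsc, r.jsc, r.ppv, r.se) == (0.0, 0.0, 0.0, 0.0)
        assert (r.rvd, r.voe) == (1.0, 1.0)
        assert r.hd == pytest.approx(math.hypot(8, 12))  # image diagonal

    def test_empty_truth_signals(self):
        with pytest.raises(EmptyTruthError):
            evaluate_case(np.ones((4, 4)), np.zeros((4, 4)))

    def test_report_matches_bruteforce_recomputation(self, rng):
        """Worked 8x8 pair: every field equals the value recomputed from the
        exhaustive oracles."""
        p_prob = rng.random((8, 8))
        g = (rng.random((8, 8)) < 0.3).astype(np.uint8)
        g[4, 4] = 1
        r = evaluate_case(p_prob, g)
        pm = (p_prob >= 0.5).astype(np.uint8)
        tp, fp, fn, tn = oracle_confusion(pm, g)
        assert r.dsc == pytest.approx(2 * tp / (2 * tp + fp + fn))
        assert r.se == pytest.approx(tp / (tp + fn))
        assert r.voe == pytest.approx(1 - tp / (tp + fp + fn))
        assert r.hd == pytest.approx(oracle_hausdorff(pm, g), abs=1e-12)

    def test_evaluate_cases_counts_exclusions(self, rng):
        g_ok = np.zeros((6, 6), dtype=np.uint8)
        g_ok[2, 2] = 1
        pairs = [
            (g_ok.astype(float), g_ok),
            (np.zeros((6, 6)), np.zeros((6, 6), dtype=np.uint8)),
        ]
        reports, excluded = metrics.evaluate_cases(pairs)
        assert len(reports) == 1 and excluded == 1


class TestAggregate:
    def _report(self, v):
        return MetricReport(v, v, v, v, v, v, v)

    def test_two_values_hand_arithmetic(self):
        agg = aggregate([self._report(0.8), self._report(0.9)])
        s = agg.stats["dsc"]
        assert s.mean == pytest.approx(0.85)
        assert s.sd == pytest.approx(0.0707, abs=5e-4)  # sample sd, n-1
        assert agg.n_cases == 2

    def test_single_report_sd_policy(self):
        agg = aggregate([self._report(0.7)])
        s = agg.stats["jsc"]
        assert s.mean == 0.7 and s.sd == 0.0 and not s.sd_defined

    def test_whiskers_exclude_outlier(self):
        agg = aggregate([self._report(v) for v in (1, 2, 3, 4, 100)])
        s = agg.stats["hd"]
        # q1=2, q3=4, 1.5*IQR fence at 7: 100 is an outlier
        assert s.whisker_high == 4.0
        assert s.whisker_low == 1.0
        assert s.q1 <= s.median <= s.q3

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            aggregate([])


def test_full_suite_matches_set_arithmetic_oracle(rng):
    """All seven metrics agree with independent exhaustive oracles on 200
    random 16x16 mask pairs (exact for the count-based metrics, 1e-12 for
    HD), and the VOE/DSC identities hold on every pair."""
    checked = 0
    while checked < 200:
        p, g = _random_pair(rng)
        if g.sum() == 0:
            continue
        checked += 1
        r = evaluate_case(p.astype(float), g)
        tp, fp, fn, tn = oracle_confusion(p, g)
        assert r.dsc == 2 * tp / (2 * tp + fp + fn)
        assert r.jsc == tp / (tp + fp + fn)
        assert r.ppv == (tp / (tp + fp) if tp + fp else 0.0)
        assert r.se == tp / (tp + fn)
        assert r.voe == 1 - r.jsc
        assert r.dsc == pytest.approx(2 * r.jsc / (1 + r.jsc), abs=1e-12)
        if p.sum():
            assert r.rvd == abs((tp + fp) - (tp + fn)) / (tp + fn)
            assert r.hd == pytest.approx(oracle_hausdorff(p, g), abs=1e-12)


def test_writers_roundtrip(tmp_path, rng):
    reports = [
        evaluate_case(rng.random((8, 8)), (rng.random((8, 8)) < 0.4).astype(np.uint8))
        for _ in range(5)
    ]
    agg = aggregate(reports)
    df = metrics.reports_to_csv(reports, tmp_path / "cases.csv")
    assert list(df.columns) == list(metrics.METRIC_NAMES)
    metrics.aggregate_to_json(agg, tmp_path / "agg.json")
    import json

    d = json.loads((tmp_path / "agg.json").read_text())
    assert d["n_cases"] == 5
    box = metrics.boxstats_to_csv(agg, tmp_path / "box.csv")
    assert set(box["metric"]) == set(metrics.METRIC_NAMES)
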