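import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pwml.evaluate import (
    MatchCriterion,
    average_precision,
    classify_fp_locations,
    compare_probabilities,
    location_percentages,
    mann_whitney,
    match_detections,
    summarize,
    sweep_thresholds,
)
from pwml.types import BACKGROUND, CORTEX, WHITE_MATTER, BoundingBox, Detection, TissueMask


def det(x, y, w=6, h=6, p=50.0, iid="a"):
    return Detection(iid, BoundingBox(x, y, x + w, y + h), p)


def box(x, y, w=6, h=6):
    return BoundingBox(x, y, x + w, y + h)


class TestMatchDetections:
    def test_identical_boxes_all_tp(self):
        truths = [box(10, 10), box(40, 40), box(70, 70)]
        dets = [det(10, 10), det(40, 40), det(70, 70)]
        tp, fp, fn = match_detections(dets, truths)
        assert len(tp) == 3 and fp == [] and fn == []

    def test_no_detections_all_fn(self):
        tp, fp, fn = match_detections([], [box(10, 10), box(40, 40)])
        assert tp == [] and fp == [] and fn == [0, 1]

    def test_each_truth_matched_at_most_once(self):
        truths = [box(10, 10)]
        dets = [det(10, 10, p=90.0), det(11, 11, p=80.0)]
        tp, fp, fn = match_detections(dets, truths)
        assert len(tp) == 1 and len(fp) == 1

    def test_greedy_equals_exhaustive_on_small_instances(self):
        """Greedy TP count equals maximum-cardinality assignment (<=6 boxes).

        Ground-truth boxes never overlap (pasted lesions are disjoint), which
        makes the IoU>=0.5 relation at most one truth per detection.
        """
        rng = np.random.default_rng(7)
        crit = MatchCriterion()
        for _ in range(40):
            truths = [
                box(20 * i + int(dx), int(dy), int(w), int(h))
                for i, (dx, dy, w, h) in enumerate(zip(
                    rng.integers(0, 6, 3), rng.integers(0, 40, 3),
                    rng.integers(4, 12, 3), rng.integers(4, 12, 3),
                ))
            ]
            dets = [
                det(int(x), int(y), int(w), int(h), p=float(p))
                for x, y, w, h, p in zip(
                    rng.integers(0, 60, 4), rng.integers(0, 60, 4),
                    rng.integers(4, 12, 4), rng.integers(4, 12, 4),
                    rng.uniform(1, 100, 4),
                )
            ]
            tp, _, _ = match_detections(dets, truths, crit)
            # oracle: exhaustive search over one-to-one assignments
            best = 0
            for perm in itertools.permutations(range(len(truths)), len(truths)):
                for subset in itertools.permutations(range(len(dets)), len(truths)):
                    n = sum(
                        crit.matches(dets[d].box, truths[t])
                        for d, t in zip(subset, perm)
                    )
                    best = max(best, n)
            assert len(tp) == best

    def test_center_mode_matches_tiny_truths(self):
        crit = MatchCriterion(mode="center_in_box")
        truths = [BoundingBox(50, 50, 53, 53)]
        dets = [det(46, 46, 10, 10)]  # IoU tiny but center covered
        tp, _, _ = match_detections(dets, truths, crit)
        assert len(tp) == 1


class TestSweep:
    def test_perfect_detection_scores(self):
        truths = {"a": [box(10, 10), box(40, 40)]}
        dets = {"a": [det(10, 10, p=90.0), det(40, 40, p=80.0)]}
        t = sweep_thresholds(dets, truths, thresholds=(20.0,))
        assert t.loc[0, "sensitivity"] == 1.0 and t.loc[0, "ppv"] == 1.0

    def test_resident_reader_arithmetic(self):
        """TP=119, FN=44, FP=4 -> sensitivity 0.730, PPV 0.967."""
        assert 119 / (119 + 44) == pytest.approx(0.730, abs=5e-4)
        truths = {"a": [box(10 * i, 10 * i, 4, 4) for i in range(163)]}
        dets = {
            "a": [det(10 * i, 10 * i, 4, 4, p=60.0) for i in range(119)]
            + [det(2000 + 10 * i, 0, 4, 4, p=60.0) for i in range(4)]
        }
        t = sweep_thresholds(dets, truths, thresholds=(20.0,))
        assert t.loc[0, "tp"] == 119 and t.loc[0, "fp"] == 4 and t.loc[0, "fn"] == 44
        assert t.loc[0, "sensitivity"] == pytest.approx(0.730, abs=5e-4)
        assert t.loc[0, "ppv"] == pytest.approx(0.967, abs=5e-4)

    def test_tp_plus_fn_conserved_and_tp_monotone(self, small_corpus_detections):
        dets_by, truths_by, _ = small_corpus_detections
        t = sweep_thresholds(dets_by, truths_by, MatchCriterion(mode="center_in_box"))
        n_truth = sum(len(v) for v in truths_by.values())
        assert (t.tp + t.fn == n_truth).all()
        assert (t.tp.diff().dropna() <= 0).all()

    def test_no_truth_flagged_as_nan(self):
        t = sweep_thresholds({"a": [det(0, 0)]}, {"a": []}, thresholds=(20.0,))
        assert math.isnan(t.loc[0, "sensitivity"])

    def test_ppv_nan_when_no_detections_survive(self):
        t = sweep_thresholds({"a": [det(0, 0, p=10.0)]}, {"a": [box(50, 50)]},
                             thresholds=(90.0,))
        assert math.isnan(t.loc[0, "ppv"])


class TestFpLocations:
    @pytest.fixture()
    def tissue(self):
        labels = np.full((100, 100), BACKGROUND, np.uint8)
        labels[:, :40] = CORTEX
        labels[:, 40:80] = WHITE_MATTER
        return {"a": TissueMask(labels)}

    def test_pure_cortex_and_wm_boxes(self, tissue):
        counts = classify_fp_locations(
            [det(10, 10, iid="a"), det(60, 10, iid="a")], tissue
        )
        assert counts["cerebral_cortex"] == 1
        assert counts["cerebral_white_matter"] == 1

    def test_straddling_box_matches_pixel_count_oracle(self, tissue):
        d = det(36, 10, 10, 10, iid="a")  # 4 cols cortex, 6 cols WM
        labels = tissue["a"].labels[d.box.slices]
        assert (labels == CORTEX).sum() < (labels == WHITE_MATTER).sum()
        counts = classify_fp_locations([d], tissue)
        assert counts["cerebral_white_matter"] == 1

    def test_tie_goes_to_cortex(self, tissue):
        d = det(35, 10, 10, 10, iid="a")  # 5 cols each
        counts = classify_fp_locations([d], tissue)
        assert counts["cerebral_cortex"] == 1

    def test_neither_label_counts_as_other(self, tissue):
        counts = classify_fp_locations([det(85, 10, iid="a")], tissue)
        assert counts["other"] == 1

    def test_missing_mask_raises(self, tissue):
        with pytest.raises(KeyError):
            classify_fp_locations([det(0, 0, iid="zzz")], tissue)


class TestMannWhitney:
    def test_identical_samples_symmetric(self):
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.u_statistic == pytest.approx(4.5)  # n1*n2/2
        assert r.p_value == pytest.approx(1.0)

    def test_complete_separation_exact_tail(self):
        """x={1,2}, y={3,4}: U=0 and exact two-sided p = 2/6."""
        r = mann_whitney([1, 2], [3, 4])
        assert r.u_statistic == 0.0
        assert r.method == "exact"
        assert r.p_value == pytest.approx(2.0 / 6.0)

    def test_exact_tail_matches_enumeration_oracle(self):
        """Exact p equals brute-force enumeration over label assignments."""
        x = [0.3, 1.7, 2.9, 4.1]
        y = [1.1, 2.3, 5.6]
        r = mann_whitney(x, y)
        pooled = np.array(x + y)
        n1 = len(x)
        u_obs = r.u_statistic
        us = []
        for idx in itertools.combinations(range(len(pooled)), n1):
            xs = pooled[list(idx)]
            ys = np.delete(pooled, list(idx))
            u = sum((a > b) for a in xs for b in ys)
            us.append(u)
        us = np.array(us, dtype=float)
        u_min = min(u_obs, n1 * (len(pooled) - n1) - u_obs)
        p_oracle = min(1.0, 2.0 * np.mean(us <= u_min))
        assert r.p_value == pytest.approx(p_oracle)

    def test_u_identity(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=8), rng.normal(size=13)
        r1, r2 = mann_whitney(x, y), mann_whitney(y, x)
        assert r1.u_statistic + r2.u_statistic == pytest.approx(8 * 13)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=9), rng.normal(size=11)
        r = mann_whitney(x, y)
        s = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert r.u_statistic == pytest.approx(s.statistic)
        assert r.p_value == pytest.approx(s.pvalue)

    def test_exact_and_normal_branches_agree(self):
        """Tie-free n1=n2=10: |p_exact - p_normal| <= 0.01."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            x, y = rng.normal(size=10), rng.normal(0.5, 1, size=10)
            exact = mann_whitney(x, y)
            assert exact.method == "exact"
            approx = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            )
            assert abs(exact.p_value - approx.pvalue) <= 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestAveragePrecision:
    def test_perfect_ranking_gives_one(self):
        truths = {"a": [box(10, 10), box(40, 40)]}
        dets = {"a": [det(10, 10, p=90.0), det(40, 40, p=80.0)]}
        assert average_precision(dets, truths) == pytest.approx(1.0)

    def test_tp_fp_tp_example(self):
        """2 truths, ranked [TP, FP, TP] -> AP = 0.5 + 0.5 * (2/3)."""
        truths = {"a": [box(10, 10), box(40, 40)]}
        dets = {"a": [det(10, 10, p=90.0), det(70, 70, p=80.0), det(40, 40, p=60.0)]}
        assert average_precision(dets, truths) == pytest.approx(0.5 + 0.5 * (2 / 3))

    def test_no_tp_gives_zero(self):
        truths = {"a": [box(10, 10)]}
        dets = {"a": [det(70, 70, p=80.0)]}
        assert average_precision(dets, truths) == 0.0

    def test_no_truth_rejected(self):
        with pytest.raises(ValueError):
            average_precision({"a": []}, {"a": []})


class TestSummary:
    def test_fp_location_percentage_arithmetic(self):
        pct = location_percentages({"cerebral_cortex": 224, "cerebral_white_matter": 37})
        assert pct == {"cerebral_cortex": 85.8, "cerebral_white_matter": 14.2}

    def test_zero_counts_give_zero_percentages(self):
        pct = location_percentages({})
        assert pct == {"cerebral_cortex": 0.0, "cerebral_white_matter": 0.0}

    def test_report_round_trips_through_csv(self, tmp_path):
        table = sweep_thresholds(
            {"a": [det(10, 10, p=90.0)]}, {"a": [box(10, 10)]},
            thresholds=(20.0, 50.0),
        )
        report = summarize(
            table,
            {20.0: {"cerebral_cortex": 224, "cerebral_white_matter": 37, "other": 0}},
        )
        for name, df in report.items():
            p = tmp_path / f"{name}.csv"
            df.to_csv(p, index=False)
            back = pd.read_csv(p)
            pd.testing.assert_frame_equal(back, df, check_dtype=False)

    def test_empty_fp_set_all_zero_rows(self):
        report = summarize(
            sweep_thresholds({}, {"a": [box(1, 1)]}, thresholds=(20.0,)),
            {20.0: {"cerebral_cortex": 0, "cerebral_white_matter": 0, "other": 0}},
        )
        row = report["fp_location"].iloc[0]
        assert row.cortex_count == 0 and row.wm_count == 0
        assert row.cortex_percent == 0.0 and row.wm_percent == 0.0

    def test_probability_comparison_medians(self):
        pc = compare_probabilities([40, 50, 60], [10, 20, 30])
        assert pc.tp_median == 50 and pc.fp_median == 20
        assert pc.p_value < 0.2
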