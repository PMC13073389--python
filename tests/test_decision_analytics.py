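"""Heuristic classification, DCA, reclassification/NRI, ROC, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ckdrisk.decision_analytics import (
    CATEGORIES,
    ReclassificationTable,
    age_egfr_score,
    c_statistic,
    calibration_table,
    classify_age_egfr,
    classify_conventional,
    decision_curve,
    load_reference_reclassification,
    net_benefit,
    nri,
    reclassification_table,
    roc_metrics,
)


class TestClassifiers:
    @pytest.mark.parametrize("age,egfr,score", [(40, 57, 97), (60, 55, 115)])
    def test_score_is_plain_sum(self, age, egfr, score):
        assert age_egfr_score(age, egfr) == score

    @pytest.mark.parametrize(
        "score,category",
        [(115, "low"), (130, "low"), (100, "moderate"), (114.9, "moderate"), (99.9, "high")],
    )
    def test_age_egfr_categories_half_open(self, score, category):
        assert classify_age_egfr(score) == category

    @pytest.mark.parametrize(
        "egfr,category", [(60, "low"), (90, "low"), (45, "moderate"), (59.9, "moderate"), (30, "high")]
    )
    def test_conventional_categories_half_open(self, egfr, category):
        assert classify_conventional(egfr) == category


class TestNetBenefit:
    def test_no_false_positives(self):
        assert net_benefit(10, 0, 100, 0.2) == pytest.approx(0.1)

    def test_unit_odds_weight_cancels(self):
        assert net_benefit(10, 10, 100, 0.5) == pytest.approx(0.0)

    def test_treat_none_is_zero(self):
        assert net_benefit(0, 0, 100, 0.3) == 0.0

    @pytest.mark.parametrize("pt", [0.0, 1.0, -0.2])
    def test_invalid_pt_rejected(self, pt):
        with pytest.raises(ValueError):
            net_benefit(1, 1, 10, pt)


class TestDecisionCurve:
    def _labels(self, n=10_000, prevalence=0.3, seed=5):
        rng = np.random.default_rng(seed)
        return (rng.random(n) < prevalence).astype(int), rng

    def test_treat_all_closed_form(self):
        y, _ = self._labels()
        curve = decision_curve(y, {})
        prev = y.mean()
        expected = prev - (1 - prev) * curve.thresholds / (1 - curve.thresholds)
        assert curve.net_benefits["treat_all"] == pytest.approx(expected)
        assert np.all(curve.net_benefits["treat_none"] == 0.0)

    def test_perfect_rule_attains_prevalence_everywhere(self):
        y, _ = self._labels()
        curve = decision_curve(y, {"perfect": y})
        assert curve.net_benefits["perfect"] == pytest.approx(np.full_like(curve.thresholds, y.mean()))

    def test_random_rule_matches_analytic_form(self):
        """A coin-flip rule treats each subject with probability q, so
        NB = q * (prev - (1-prev) * pt/(1-pt)) in expectation."""
        y, rng = self._labels()
        q = 0.5
        rule = (rng.random(len(y)) < q).astype(int)
        curve = decision_curve(y, {"random": rule})
        prev = y.mean()
        expected = q * (prev - (1 - prev) * curve.thresholds / (1 - curve.thresholds))
        # Monte-Carlo error on TP/N and FP/N is O(1/sqrt(n)); odds weight <= 1.5
        assert np.max(np.abs(curve.net_benefits["random"] - expected)) < 5 / np.sqrt(len(y))

    def test_net_benefit_bounded_by_prevalence(self):
        y, rng = self._labels()
        rules = {f"r{k}": (rng.random(len(y)) < 0.3).astype(int) for k in range(3)}
        curve = decision_curve(y, rules)
        for nb in curve.net_benefits.values():
            assert np.all(nb <= curve.prevalence + 1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            decision_curve([0, 1], {"r": [1]})


REF_EVENTS = np.array([[8330, 5375, 0], [1568, 4698, 1013], [0, 1075, 317]])
REF_NON_EVENTS = np.array([[71159, 10510, 0], [8468, 6746, 741], [0, 894, 94]])


def _expand(matrix, outcome):
    conv, new, y = [], [], []
    for i, row_cat in enumerate(CATEGORIES):
        for j, col_cat in enumerate(CATEGORIES):
            conv += [row_cat] * matrix[i, j]
            new += [col_cat] * matrix[i, j]
            y += [outcome] * matrix[i, j]
    return conv, new, y


@pytest.fixture(scope="module")
def reference():
    return load_reference_reclassification()


class TestReclassification:
    def test_fixture_matches_frozen_counts(self, reference):
        assert np.array_equal(reference.events, REF_EVENTS)
        assert np.array_equal(reference.non_events, REF_NON_EVENTS)

    def test_event_summary_counts(self, reference):
        s = reference.summary()["events"]
        assert (s["correct"], s["incorrect"], s["net"]) == (6388, 2643, 3745)

    def test_non_event_summary_counts(self, reference):
        s = reference.summary()["non_events"]
        assert (s["correct"], s["incorrect"], s["net"]) == (9362, 11251, -1889)

    def test_nri_reproduces_reference_percentages(self, reference):
        additive, absolute = nri(reference)
        assert round(additive, 2) == 14.82
        assert round(absolute, 2) == 1.53

    def test_rebuilt_from_individual_categories(self, reference):
        conv_e, new_e, y_e = _expand(REF_EVENTS, 1)
        conv_ne, new_ne, y_ne = _expand(REF_NON_EVENTS, 0)
        rt = reclassification_table(conv_e + conv_ne, new_e + new_ne, y_e + y_ne)
        assert np.array_equal(rt.events, reference.events)
        assert np.array_equal(rt.non_events, reference.non_events)

    def test_diagonal_table_has_zero_summaries(self):
        rt = ReclassificationTable(
            events=np.diag([5, 6, 7]), non_events=np.diag([8, 9, 10])
        )
        s = rt.summary()
        assert (s.loc["net"] == 0).all() and (s.loc["correct"] == 0).all()
        assert nri(rt) == (0.0, 0.0)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 20), min_size=18, max_size=18))
    def test_nri_matches_direct_enumeration(self, flat):
        """NRI from the count matrices equals brute-force counting of
        up/down moves over the expanded individuals."""
        events = np.array(flat[:9]).reshape(3, 3)
        non_events = np.array(flat[9:]).reshape(3, 3)
        if events.sum() == 0 or non_events.sum() == 0:
            return
        rt = ReclassificationTable(events=events, non_events=non_events)
        idx = {c: k for k, c in enumerate(CATEGORIES)}
        up_e = down_e = up_ne = down_ne = 0
        for matrix, outcome in ((events, 1), (non_events, 0)):
            conv, new, _ = _expand(matrix, outcome)
            for c, n in zip(conv, new):
                if idx[n] > idx[c]:
                    if outcome:
                        up_e += 1
                    else:
                        up_ne += 1
                elif idx[n] < idx[c]:
                    if outcome:
                        down_e += 1
                    else:
                        down_ne += 1
        expected_add = 100 * (
            (up_e - down_e) / events.sum() + (down_ne - up_ne) / non_events.sum()
        )
        expected_abs = 100 * ((up_e - down_e) + (down_ne - up_ne)) / (
            events.sum() + non_events.sum()
        )
        additive, absolute = nri(rt)
        assert additive == pytest.approx(expected_add)
        assert absolute == pytest.approx(expected_abs)

    def test_zero_denominator_rejected(self):
        rt = ReclassificationTable(events=np.zeros((3, 3), int), non_events=np.diag([1, 1, 1]))
        with pytest.raises(ValueError):
            nri(rt)


class TestDiscrimination:
    def test_perfect_separation(self):
        res = roc_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == 1.0 and res.youden == 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(17)
        n = 10_000
        y = (rng.random(n) < 0.5).astype(int)
        s = rng.random(n)
        res = roc_metrics(s, y)
        se = np.sqrt(1 / (12 * n * 0.25))  # large-sample SE of the rank AUC
        assert abs(res.auc - 0.5) <= 3 * se

    def test_auc_equals_c_statistic(self):
        rng = np.random.default_rng(3)
        y = (rng.random(500) < 0.4).astype(int)
        s = rng.integers(0, 10, size=500).astype(float)  # heavy ties
        res = roc_metrics(s, y)
        assert res.auc == pytest.approx(c_statistic(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_metrics([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError):
            c_statistic([0.1, 0.2], [0, 0])

    def test_all_ties_give_half(self):
        assert c_statistic([1.0, 1.0, 1.0, 1.0], [1, 0, 1, 0]) == 0.5

    def test_hand_case(self):
        assert c_statistic([3, 2, 1], [1, 0, 0]) == 1.0

    def test_c_statistic_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(8)
        n = 200
        y = (rng.random(n) < 0.5).astype(int)
        s = rng.integers(0, 50, size=n).astype(float)
        pos, neg = s[y == 1], s[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert c_statistic(s, y) == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


class TestCalibration:
    def test_self_consistency_on_uniform_predictions(self):
        rng = np.random.default_rng(9)
        n = 100_000
        p = rng.random(n)
        y = (rng.random(n) < p).astype(int)
        table = calibration_table(p, y, n_strata=10)
        assert table["count"].sum() == n
        for _, row in table.iterrows():
            se = np.sqrt(row["mean_predicted"] * (1 - row["mean_predicted"]) / row["count"])
            assert abs(row["mean_predicted"] - row["observed_rate"]) <= 3 * se

    def test_constant_prediction_single_stratum(self):
        rng = np.random.default_rng(10)
        y = (rng.random(4000) < 0.5).astype(int)
        table = calibration_table(np.full(4000, 0.5), y, n_strata=10)
        assert len(table) == 1
        assert table["observed_rate"].iloc[0] == pytest.approx(0.5, abs=0.03)

    def test_degenerate_all_zero(self):
        table = calibration_table(np.zeros(100), np.zeros(100, int), n_strata=5)
        assert table["mean_predicted"].iloc[0] == 0.0
        assert table["observed_rate"].iloc[0] == 0.0

    def test_out_of_range_predictions_rejected(self):
        with pytest.raises(ValueError):
            calibration_table([1.2, 0.5], [1, 0])
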