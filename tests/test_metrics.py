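"""Evaluation statistics: confusion metrics, kappa, correlation, delay,
incidence — each against an independent oracle."""

from __future__ import annotations

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from habsi.metrics import (
    ConfusionMatrix,
    cohen_kappa,
    compute_metrics,
    count_correlation,
    delay_stats,
    incidence,
    incidence_by_stratum,
    patient_level_confusion,
    round_half_up,
)
from habsi.records import Classification, HabsiEvent

from conftest import ts


def _event(eid, onset, confirm):
    return HabsiEvent(
        event_id=eid, patient_id=f"P{eid}", episode_id="E", onset_ts=ts(onset),
        organisms=(), classification=Classification.CSEP,
        source_specimens=(), confirmation_ts=None if confirm is None else ts(confirm),
    )


class TestConfusion:
    def test_simple_agreement(self):
        cm = patient_level_confusion({"A"}, {"A"}, {"A", "B"})
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 0, 0, 1)

    def test_simple_disagreement(self):
        cm = patient_level_confusion({"A"}, {"B"}, {"A", "B"})
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (0, 1, 1, 0)

    def test_unknown_patient_is_fatal(self):
        with pytest.raises(ValueError, match="outside the population"):
            patient_level_confusion({"Z"}, {"A"}, {"A"})

    def test_random_assignment_matches_set_algebra_oracle(self):
        rng = random.Random(5)
        pop = {f"P{i}" for i in range(200)}
        detected = {p for p in pop if rng.random() < 0.3}
        reference = {p for p in pop if rng.random() < 0.25}
        cm = patient_level_confusion(detected, reference, pop)
        assert cm.tp == sum(1 for p in pop if p in detected and p in reference)
        assert cm.fp == sum(1 for p in pop if p in detected and p not in reference)
        assert cm.fn == sum(1 for p in pop if p not in detected and p in reference)
        assert cm.tn == sum(1 for p in pop if p not in detected and p not in reference)
        assert cm.total == len(pop)


class TestComputeMetrics:
    def test_perfect_table(self):
        m = compute_metrics(ConfusionMatrix(tp=10, fn=0, fp=0, tn=90))
        assert m.sensitivity.pct == 100.0 and m.specificity.pct == 100.0
        assert m.ppv.pct == 100.0 and m.npv.pct == 100.0
        assert m.kappa.value == pytest.approx(1.0)

    def test_kappa_one_iff_no_errors(self):
        assert cohen_kappa(ConfusionMatrix(5, 0, 0, 5)).value == pytest.approx(1.0)
        assert cohen_kappa(ConfusionMatrix(5, 1, 0, 5)).value < 1.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        tp=st.integers(0, 50), fn=st.integers(0, 50),
        fp=st.integers(0, 50), tn=st.integers(0, 50),
    )
    def test_kappa_matches_hand_formula_and_sklearn(self, tp, fn, fp, tn):
        n = tp + fn + fp + tn
        if n == 0:
            return
        cm = ConfusionMatrix(tp, fn, fp, tn)
        po = (tp + tn) / n
        pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
        est = cohen_kappa(cm)
        if pe == 1.0:
            assert est.value is None
            return
        assert est.value == pytest.approx((po - pe) / (1 - pe), abs=1e-12)
        # independent route: scikit-learn on the expanded label vectors
        y_true = [1] * (tp + fn) + [0] * (fp + tn)
        y_pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        if len(set(y_true)) > 1 or len(set(y_pred)) > 1:
            assert est.value == pytest.approx(cohen_kappa_score(y_true, y_pred), abs=1e-9)

    def test_swapping_labels_swaps_paired_metrics(self):
        cm = ConfusionMatrix(tp=30, fn=5, fp=8, tn=100)
        m, m_sw = compute_metrics(cm), compute_metrics(cm.swapped())
        assert m.sensitivity.value == pytest.approx(m_sw.specificity.value)
        assert m.specificity.value == pytest.approx(m_sw.sensitivity.value)
        assert m.ppv.value == pytest.approx(m_sw.npv.value)
        assert m.npv.value == pytest.approx(m_sw.ppv.value)
        assert m.kappa.value == pytest.approx(m_sw.kappa.value)

    def test_zero_denominator_flagged_undefined_not_nan(self):
        m = compute_metrics(ConfusionMatrix(tp=0, fn=0, fp=3, tn=97))
        assert m.sensitivity.value is None
        assert not m.sensitivity.defined
        assert m.specificity.defined

    def test_confidence_intervals_contain_estimate_within_unit_interval(self):
        for cells in [(160, 3, 7, 17824), (1, 1, 1, 1), (10, 0, 3, 50)]:
            m = compute_metrics(ConfusionMatrix(*cells))
            for est in (m.sensitivity, m.specificity, m.ppv, m.npv):
                assert 0.0 <= est.ci_low <= est.value <= est.ci_high <= 1.0

    def test_kappa_near_zero_under_independence(self):
        rng = np.random.default_rng(42)
        n = 20000
        a = rng.random(n) < 0.3
        b = rng.random(n) < 0.3
        cm = ConfusionMatrix(
            tp=int((a & b).sum()), fn=int((a & ~b).sum()),
            fp=int((~a & b).sum()), tn=int((~a & ~b).sum()),
        )
        assert abs(cohen_kappa(cm).value) < 0.03


class TestCorrelation:
    def test_identical_and_negated_series(self):
        a = [3, 9, 1, 7, 5]
        r, _ = count_correlation(a, a)
        assert r == pytest.approx(1.0)
        r, _ = count_correlation(a, [-x for x in a])
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 60, size=20).astype(float)
        b = a * 0.9 + rng.normal(0, 4, size=20)
        r, _ = count_correlation(a, b)
        oracle = float(
            np.sum((a - a.mean()) * (b - b.mean()))
            / math.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        )
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            count_correlation([1, 1, 1], [1, 2, 3])


class TestDelayStats:
    def test_single_event_delay_in_whole_days(self):
        df = delay_stats([_event("1", "2012-10-15 08:00", "2012-10-20 16:00")])
        assert df.loc[df.month == "2012-10", "mean"].item() == 5

    def test_period_mean_is_unweighted_mean_of_monthly_means(self):
        events = [
            # October: delays 3 and 5 -> monthly mean 4
            _event("1", "2012-10-01 08:00", "2012-10-04 08:00"),
            _event("2", "2012-10-10 08:00", "2012-10-15 08:00"),
            # November: one delay of 6 -> monthly mean 6
            _event("3", "2012-11-01 08:00", "2012-11-07 08:00"),
        ]
        df = delay_stats(events)
        assert df.loc[df.month == "period", "mean"].item() == pytest.approx(5.0)

    def test_matches_brute_force_grouping_oracle(self):
        rng = random.Random(11)
        events, oracle = [], {}
        for k in range(60):
            month = rng.choice(["2012-10", "2012-11", "2012-12"])
            day = rng.randint(1, 20)
            delay = rng.randint(0, 30)
            from datetime import timedelta

            onset = ts(f"{month}-{day:02d} 08:00")
            confirm = onset + timedelta(days=delay)
            events.append(_event(str(k), onset.isoformat(" "), confirm.isoformat(" ")))
            oracle.setdefault(confirm.strftime("%Y-%m"), []).append(delay)
        df = delay_stats(events).set_index("month")
        for month, delays in oracle.items():
            assert df.loc[month, "mean"] == pytest.approx(np.mean(delays))
            assert df.loc[month, "n"] == len(delays)
        assert df.loc["period", "mean"] == pytest.approx(
            np.mean([np.mean(v) for v in oracle.values()])
        )

    def test_negative_delay_is_fatal(self):
        with pytest.raises(Exception):
            delay_stats([_event("1", "2012-10-15 08:00", "2012-10-10 08:00")])


class TestIncidence:
    def test_direct_arithmetic(self):
        assert incidence(2, 1000) == pytest.approx(2.0)
        assert incidence(0, 500) == 0.0

    def test_stratified_table_with_pooled_and_range(self):
        counts = {"D1": 4, "D2": 0, "D3": 9}
        denoms = {"D1": 800, "D2": 1200, "D3": 500, "D4": 0}
        df = incidence_by_stratum(counts, denoms)
        d1 = df.loc[df.stratum == "D1", "rate_per_1000"].item()
        assert d1 == pytest.approx(1000 * 4 / 800)
        assert df.loc[df.stratum == "D4", "rate_per_1000"].isna().all()
        pooled = df.loc[df.stratum == "pooled"]
        assert pooled["rate_per_1000"].item() == pytest.approx(1000 * 13 / 2500)
        assert pooled["rate_max"].item() == pytest.approx(1000 * 9 / 500)


def test_round_half_up_display_rule():
    assert round_half_up(98.155) == 98.16
    assert round_half_up(0.965) == 0.97
    assert round_half_up(2.5, 0) == 3.0
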