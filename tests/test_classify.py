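"""Warm-glow threshold and the three-way rationality classification."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from conftest import make_respondent_row
from warmglow import (
    RationalityClassifier,
    TREATMENTS,
    belief_from_guess,
    classify_cohort,
    classify_respondent,
    crra_from_investment,
    expected_utility,
    outcome_probabilities,
    risk_neutral_threshold,
    warm_glow_threshold,
)

RHO_EXAMPLE = math.log(1.5) / math.log(3.5)  # interior CRRA at q=100


def oracle_eu_gap(c: float, rho: float, p: float, tid: str) -> float:
    """Independent EU(contribute)+glow minus EU(defect), written from the
    payoff table: success/fail pay (3, 0) euros to contributors (2 on fail
    in T3) and (4, 1) to defectors."""
    spec = TREATMENTS[tid]
    n, T = spec.n_others, spec.threshold

    def tail(k_min):
        return sum(
            math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(k_min, n + 1)
        )

    def u(x):
        return x ** (1 - rho) / (1 - rho) if rho != 1 else math.log(x)

    cf = 2.0 if tid == "T3" else 0.0
    pc, pd_ = tail(T - 1), tail(T)
    eu_c = pc * u(3.0 + c) + (1 - pc) * u(cf + c)
    eu_d = pd_ * u(4.0) + (1 - pd_) * u(1.0)
    return eu_c - eu_d


class TestExpectedUtility:
    def test_certain_failure_defection_pays_one_euro(self):
        bel = outcome_probabilities(0.0, "T1")
        assert expected_utility(False, 0.0, 0.0, bel, "T1") == pytest.approx(1.0)

    def test_certain_success_contribution_pays_three_euros(self):
        bel = outcome_probabilities(1.0, "T2")
        assert expected_utility(True, 0.0, 0.0, bel, "T2") == pytest.approx(3.0)

    def test_risk_neutral_contribution_value_worked_example(self):
        bel = outcome_probabilities(20 / 49, "T2")
        # 3 * P(X >= 24), frozen from the explicit binomial summation
        assert expected_utility(True, 0.0, 0.0, bel, "T2") == pytest.approx(
            0.4636103038, abs=1e-9
        )

    def test_negative_warm_glow_rejected(self):
        bel = outcome_probabilities(0.5, "T1")
        with pytest.raises(ValueError, match="non-negative"):
            expected_utility(True, -0.5, 0.0, bel, "T1")


class TestWarmGlowThreshold:
    def test_worked_example_reproduces_86_cents(self):
        """q=100 tokens and a guess of 20 of 49 others in T2 require a
        warm glow of about 0.86 EUR to rationalize contributing."""
        rho = crra_from_investment(100).rho
        bel = outcome_probabilities(belief_from_guess(20, "T2"), "T2")
        C = warm_glow_threshold(rho, bel, "T2")
        assert C == pytest.approx(0.86, abs=0.02)
        # and the returned threshold solves the independently written
        # indifference equation
        assert oracle_eu_gap(C, rho, 20 / 49, "T2") == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("tid", ["T1", "T2", "T3"])
    @pytest.mark.parametrize("p", np.linspace(0.02, 0.98, 13))
    def test_risk_neutral_matches_closed_form(self, tid, p):
        spec = TREATMENTS[tid]
        bel = outcome_probabilities(p, spec)
        C = warm_glow_threshold(0.0, bel, spec)
        if tid == "T3":
            expected = (
                3 * bel.prob_success_if_defect - bel.prob_success_if_contribute - 1
            )
        else:
            expected = 1 - 3 * bel.prob_pivot
        assert C == pytest.approx(expected, abs=1e-9)
        assert risk_neutral_threshold(p, spec) == pytest.approx(expected, abs=1e-12)

    def test_negative_threshold_when_pivotality_is_high(self):
        # fair-coin beliefs in the small group: 1 - 3 * 0.375 = -0.125,
        # so selfish contribution is rational
        C = warm_glow_threshold(0.0, outcome_probabilities(0.5, "T1"), "T1")
        assert C == pytest.approx(-0.125, abs=1e-9)

    @pytest.mark.parametrize("rho", [1.0, 1.5, 3.0])
    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_strictly_positive_under_strong_aversion_in_risky_treatments(
        self, rho, p
    ):
        """With rho >= 1 a failed contribution (0 EUR) has utility -inf,
        so some positive glow is always required in T1/T2."""
        for tid in ("T1", "T2"):
            bel = outcome_probabilities(p, tid)
            assert warm_glow_threshold(rho, bel, tid) > 0.0

    def test_decreasing_in_pivot_probability(self):
        """More perceived pivotality makes contribution cheaper to
        rationalize: along each monotone branch of the pivot probability
        (p below / above its modal belief), C moves opposite to the pivot
        probability (risky treatment, fixed preferences)."""
        mode = 24 / 49
        for rho in (0.0, RHO_EXAMPLE, 0.8):
            grid = np.linspace(0.05, 0.95, 19)
            cs = [
                warm_glow_threshold(rho, outcome_probabilities(p, "T2"), "T2")
                for p in grid
            ]
            low = [c for p, c in zip(grid, cs) if p <= mode]   # pivot rising
            high = [c for p, c in zip(grid, cs) if p >= mode]  # pivot falling
            assert all(a > b for a, b in zip(low, low[1:]))
            assert all(a < b for a, b in zip(high, high[1:]))


class TestClassifyRespondent:
    def test_worked_example_contributor_is_altruistic(self):
        row = make_respondent_row(g2_contribute=True)
        res = classify_respondent(row)
        assert res.type_label == "type_ii"
        assert res.C == pytest.approx(0.86, abs=0.02)
        assert not res.selfish_action

    def test_high_pivotality_contributor_is_selfish_consistent(self):
        row = make_respondent_row(
            treatment="T1", g1_invest=200, g3_guess=2, g2_contribute=True
        )
        res = classify_respondent(row)
        assert res.selfish_action and res.type_label == "type_i"
        assert res.C < 0

    def test_high_pivotality_defector_has_negative_preferences(self):
        row = make_respondent_row(
            treatment="T1", g1_invest=200, g3_guess=2, g2_contribute=False
        )
        assert classify_respondent(row).type_label == "type_iii"

    def test_selfish_action_iff_nonpositive_threshold(self, small_cohort):
        out = RationalityClassifier().fit(small_cohort).transform(small_cohort)
        assert ((out["C"] <= 0) == out["selfish_action"]).all()
        assert set(out["type_label"]) <= {"type_i", "type_ii", "type_iii"}


class TestClassifyCohort:
    def test_three_archetypes_partition(self):
        rows = pd.DataFrame(
            [
                make_respondent_row(respondent_id="a", g2_contribute=True),
                make_respondent_row(
                    respondent_id="b", treatment="T1", g1_invest=200,
                    g3_guess=2, g2_contribute=True,
                ),
                make_respondent_row(
                    respondent_id="c", treatment="T1", g1_invest=200,
                    g3_guess=2, g2_contribute=False,
                ),
            ]
        )
        tidy, summary = classify_cohort(rows)
        assert sorted(tidy["type_label"]) == ["type_i", "type_ii", "type_iii"]
        assert summary.loc["total", "count"] == 3
        assert summary["count"][:-1].sum() == 3

    def test_type_counts_partition_cohort(self, small_cohort):
        tidy, summary = classify_cohort(small_cohort)
        assert len(tidy) == len(small_cohort)
        assert summary["count"][:-1].sum() == len(small_cohort)
        assert summary["total_pct"][:-1].sum() == pytest.approx(100.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            classify_cohort(pd.DataFrame())


class TestSklearnInterface:
    def test_clone_and_params_roundtrip(self):
        clf = RationalityClassifier(validate=False)
        assert clone(clf).get_params() == {"validate": False}

    def test_transform_appends_classification_columns(self, small_cohort):
        out = RationalityClassifier().fit_transform(small_cohort)
        for col in ("rho", "p", "prob_pivot", "C", "selfish_action", "type_label"):
            assert col in out.columns
        assert len(out) == len(small_cohort)

    def test_schema_violation_rejected(self):
        clf = RationalityClassifier()
        with pytest.raises((ValueError, TypeError)):
            clf.fit(pd.DataFrame({"g1_invest": [100]}))
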