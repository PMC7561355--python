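"""Closed-form scenario arithmetic: z-tests, replication rate, FPR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replirate import (
    ScenarioParams,
    StudyDesign,
    UndefinedRateError,
    all_significant_prob,
    any_of_m_effects_prob,
    critical_value,
    false_positive_rate,
    replication_rate,
    ztest_rejection_prob,
)


@pytest.mark.parametrize(
    "alpha, tails, expected, tol",
    [
        (0.05, "two_sided", 1.96, 5e-3),
        (0.5, "one_sided", 0.0, 1e-12),
        (0.05, "one_sided", 1.6449, 1e-4),
    ],
)
def test_critical_value(alpha, tails, expected, tol):
    assert critical_value(alpha, tails) == pytest.approx(expected, abs=tol)


def test_critical_value_bisection_oracle():
    """Independent check: invert the standard normal CDF by bisection."""
    from scipy.stats import norm

    lo, hi = 0.0, 10.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if norm.sf(mid) > 0.05:
            lo = mid
        else:
            hi = mid
    assert critical_value(0.05, "one_sided") == pytest.approx((lo + hi) / 2, abs=1e-10)


@pytest.mark.parametrize("alpha", [0.005, 0.05, 0.2])
def test_critical_value_defines_rejection_mass(alpha):
    from scipy.stats import norm

    c1 = critical_value(alpha, "one_sided")
    c2 = critical_value(alpha, "two_sided")
    assert norm.sf(c1) == pytest.approx(alpha, abs=1e-12)
    assert 2 * norm.sf(c2) == pytest.approx(alpha, abs=1e-12)


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
def test_critical_value_domain_error(bad):
    with pytest.raises(ValueError):
        critical_value(bad, "one_sided")


class TestZTestRejection:
    def test_null_returns_alpha_exactly(self):
        for tails in ("one_sided", "two_sided"):
            design = StudyDesign(effect_size=0.0, alpha_nominal=0.05, tails=tails)
            assert ztest_rejection_prob(design) == pytest.approx(0.05, abs=1e-10)

    def test_two_sample_power_closed_form(self):
        # 1 - Phi(1.6449 - 0.8*sqrt(10)) for d=0.8, n=20 per group
        design = StudyDesign(effect_size=0.8, alpha_nominal=0.05, tails="one_sided")
        assert ztest_rejection_prob(design) == pytest.approx(0.812, abs=5e-3)

    def test_one_sample_power_matches_raw_data_simulation(self):
        design = StudyDesign(
            test_form="one_sample", n_per_group=20, effect_size=0.5,
            alpha_nominal=0.005, tails="one_sided",
        )
        analytic = ztest_rejection_prob(design)
        assert 0.0 < analytic < 1.0
        rng = np.random.default_rng(20260930)
        c = critical_value(0.005, "one_sided")
        hits = 0
        n_reps = 1_000_000
        chunk = 200_000
        for _ in range(n_reps // chunk):
            x = rng.standard_normal((chunk, 20)) + 0.5
            z = x.mean(axis=1) * math.sqrt(20)  # known unit variance
            hits += int((z > c).sum())
        p_hat = hits / n_reps
        se = math.sqrt(analytic * (1 - analytic) / n_reps)
        assert abs(p_hat - analytic) < 3 * se

    @given(
        d=st.floats(0.0, 1.5),
        d2=st.floats(0.0, 1.5),
        n=st.integers(5, 100),
        n2=st.integers(5, 100),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_effect_and_sample_size(self, d, d2, n, n2):
        lo_d, hi_d = sorted((d, d2))
        lo_n, hi_n = sorted((n, n2))
        base = StudyDesign(n_per_group=lo_n, effect_size=lo_d)
        assert ztest_rejection_prob(base.with_effect(hi_d)) >= ztest_rejection_prob(base)
        more_n = StudyDesign(n_per_group=hi_n, effect_size=max(lo_d, 0.1))
        fewer_n = StudyDesign(n_per_group=lo_n, effect_size=max(lo_d, 0.1))
        assert ztest_rejection_prob(more_n) >= ztest_rejection_prob(fewer_n) - 1e-12

    def test_monotone_in_alpha(self):
        probs = [
            ztest_rejection_prob(StudyDesign(effect_size=0.3, alpha_nominal=a))
            for a in (0.001, 0.01, 0.05, 0.2)
        ]
        assert probs == sorted(probs)


class TestReplicationRate:
    def test_limits(self):
        assert replication_rate(ScenarioParams(0.0, 0.05, 0.9)) == 0.05
        assert replication_rate(ScenarioParams(1.0, 0.05, 0.9)) == 0.90

    def test_hand_arithmetic_point(self):
        # (0.1*0.9*0.9 + 0.9*0.05*0.05) / (0.1*0.9 + 0.9*0.05) = 0.61667
        s = ScenarioParams(0.1, 0.05, 0.9, alpha2=0.05, power2=0.9)
        assert replication_rate(s) == pytest.approx(0.61667, abs=1e-5)

    def test_undefined_corners_raise(self):
        with pytest.raises(UndefinedRateError):
            replication_rate(ScenarioParams(0.0, 0.0, 0.9))
        with pytest.raises(UndefinedRateError):
            replication_rate(ScenarioParams(1.0, 0.05, 0.0))
        with pytest.raises(UndefinedRateError):
            false_positive_rate(0.0, 0.0, 0.9)
        with pytest.raises(UndefinedRateError):
            false_positive_rate(1.0, 0.05, 0.0)

    @given(
        pi=st.floats(0.0, 1.0),
        a1=st.floats(0.001, 1.0),
        p1=st.floats(0.001, 1.0),
        a2=st.floats(0.01, 0.2),
        p2=st.floats(0.3, 0.99),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_between_alpha2_and_power2(self, pi, a1, p1, a2, p2):
        rr = replication_rate(ScenarioParams(pi, a1, p1, a2, p2))
        assert min(a2, p2) - 1e-12 <= rr <= max(a2, p2) + 1e-12

    @given(
        a1=st.floats(0.001, 0.3),
        p1=st.floats(0.35, 1.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rr_increasing_fpr_decreasing_in_base_rate(self, a1, p1):
        # requires power1 > alpha1 and power2 > alpha2
        pis = np.linspace(0.0, 1.0, 11)
        rrs = [replication_rate(ScenarioParams(p, a1, p1)) for p in pis]
        fprs = [false_positive_rate(p, a1, p1) for p in pis]
        assert all(b > a for a, b in zip(rrs, rrs[1:]))
        assert all(b < a for a, b in zip(fprs, fprs[1:]))

    def test_worst_case_hacking_approaches_linear_interpolation(self):
        for pi in (0.1, 0.3, 0.7):
            rr = replication_rate(ScenarioParams(pi, 1.0, 1.0, 0.05, 0.9))
            assert rr == pytest.approx(pi * 0.9 + (1 - pi) * 0.05, abs=1e-12)


class TestFalsePositiveRate:
    def test_endpoints(self):
        assert false_positive_rate(0.0, 0.05, 0.9) == 1.0
        assert false_positive_rate(1.0, 0.05, 0.9) == 0.0

    def test_hand_arithmetic_point(self):
        # 0.025 / 0.475
        assert false_positive_rate(0.5, 0.05, 0.9) == pytest.approx(0.05263, abs=1e-5)

    @given(
        pi=st.floats(0.01, 0.99),
        a1=st.floats(0.001, 1.0),
        p1=st.floats(0.001, 1.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_true_positive_share_is_exact_complement(self, pi, a1, p1):
        fpr = false_positive_rate(pi, a1, p1)
        tp_share = pi * p1 / ((1 - pi) * a1 + pi * p1)
        assert fpr + tp_share == pytest.approx(1.0, abs=1e-12)


def test_all_significant_prob():
    # a run of five positives at single-study power 0.36 is a 0.006 event
    assert round(all_significant_prob(0.36, 5), 3) == 0.006
    assert all_significant_prob(1.0, 7) == 1.0
    assert all_significant_prob(0.5, 3) == pytest.approx(0.125)


def test_any_of_m_effects_prob():
    # seven ANOVA effect tests under a global null: ~30% hit rate at alpha=5%
    assert any_of_m_effects_prob(0.05, 7) == pytest.approx(0.3017, abs=1e-4)
    assert any_of_m_effects_prob(0.07, 1) == pytest.approx(0.07)
    assert any_of_m_effects_prob(0.005, 7) == pytest.approx(0.03448, abs=1e-4)
    # complement-product oracle
    prod = 1.0
    for _ in range(7):
        prod *= 1 - 0.005
    assert any_of_m_effects_prob(0.005, 7) == pytest.approx(1 - prod, abs=1e-15)


def test_scenario_params_validation():
    with pytest.raises(ValueError):
        ScenarioParams(-0.1, 0.05, 0.9)
    with pytest.raises(ValueError):
        ScenarioParams(0.5, 0.05, 0.9, alpha2=0.0)
    # QRP-inflated effective rates above nominal are legal inputs
    ScenarioParams(0.5, 0.34, 0.95)


def test_study_design_validation():
    with pytest.raises(ValueError):
        StudyDesign(n_per_group=1)
    with pytest.raises(ValueError):
        StudyDesign(effect_size=-0.2)
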