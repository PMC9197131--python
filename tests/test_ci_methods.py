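import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medboot import (
    CIRequest,
    bcbci,
    bias_z,
    gate_thresholds,
    pbci,
    rbcbci,
    stbcbci,
    wbcbci,
    winsorized_mean,
)

from conftest import make_dist


def random_dist(seed, B=400, ab_quantile=None):
    """Continuous distribution; source estimate placed so that exactly
    int(ab_quantile * B) estimates fall strictly below it."""
    rng = np.random.default_rng(seed)
    est = np.sort(rng.normal(size=B))
    if ab_quantile is None:
        ab = 0.0
    else:
        k = int(ab_quantile * B)
        k = min(max(k, 1), B - 1)
        ab = float(est[k - 1] + est[k]) / 2.0
    return make_dist(est, source_ab_hat=ab)


class TestBiasZ:
    def test_reference_at_median_gives_zero(self):
        dist = make_dist(np.arange(1.0, 5001.0))
        # 2500 of 5000 estimates below the reference -> Phi^-1(0.5) = 0
        assert bias_z(dist, 2500.5) == 0.0

    def test_matches_normal_quantile_oracle(self):
        dist = make_dist(np.arange(1.0, 5001.0))
        # 2870 estimates below -> Phi^-1(0.574), frozen from the quantile oracle
        assert bias_z(dist, 2870.5) == pytest.approx(0.1865671818, abs=1e-9)

    def test_reference_below_all_estimates_is_clamped(self):
        dist = make_dist(np.arange(1.0, 5001.0))
        # count clamped to 1 -> Phi^-1(1/5000), frozen from the quantile oracle
        assert bias_z(dist, -100.0) == pytest.approx(-3.5400837992, abs=1e-9)
        assert bias_z(dist, 1e9) == pytest.approx(3.5400837992, abs=1e-9)

    def test_ties_with_reference_are_not_counted(self):
        dist = make_dist([1.0, 2.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        # strictly-below count is 1, not 4
        assert bias_z(dist, 2.0) == pytest.approx(bias_z(dist, 1.5))


class TestPercentileInterval:
    def test_limits_at_conventional_order_statistics(self):
        dist = make_dist(np.arange(1.0, 5001.0))
        ci = pbci(dist, CIRequest(level=0.95))
        assert (ci.lower, ci.upper) == (125.0, 4875.0)
        assert ci.z_adj_hat is None
        assert ci.lower_percentile == pytest.approx(0.025)
        assert ci.upper_percentile == pytest.approx(0.975)

    def test_supplementary_comparison_level(self):
        dist = make_dist(np.arange(1.0, 5001.0))
        ci = pbci(dist, CIRequest(level=0.923))
        assert ci.level == 0.923
        assert ci.lower == np.ceil(0.0385 * 5000 - 1e-9)

    def test_symmetric_toy_distribution_gives_symmetric_interval(self, symmetric_dist):
        ci = pbci(symmetric_dist, CIRequest(level=0.5))
        assert ci.lower == -ci.upper


class TestBiasCorrectedIntervals:
    def test_zero_correction_collapses_to_percentile(self):
        dist = random_dist(0, ab_quantile=0.5)
        p = pbci(dist)
        for fn in (bcbci, rbcbci):
            ci = fn(dist)
            assert ci.z_adj_hat == 0.0
            assert (ci.lower, ci.upper) == (p.lower, p.upper)

    def test_double_shift_percentiles_match_normal_cdf_oracle(self):
        # z_adj = 0.1 at the 95% level; frozen Phi(0.2 -/+ 1.959964)
        dist = make_dist(np.arange(1.0, 1001.0), source_ab_hat=540.5)
        ci = bcbci(dist)  # 540 of 1000 below -> z = Phi^-1(0.54) ~ 0.10043
        z = ci.z_adj_hat
        from scipy.special import ndtr, ndtri

        assert ci.lower_percentile == pytest.approx(ndtr(2 * z + ndtri(0.025)))
        assert ci.upper_percentile == pytest.approx(ndtr(2 * z + ndtri(0.975)))

    def test_frozen_shift_values_at_z_one_tenth(self):
        from scipy.special import ndtri

        # direct check of the limit mapping at z_adj exactly 0.1
        from medboot.ci_methods import _shifted_interval

        dist = make_dist(np.arange(1.0, 5001.0))
        double = _shifted_interval(dist, 0.1, CIRequest(), 2.0, "BC")
        single = _shifted_interval(dist, 0.1, CIRequest(), 1.0, "rBC")
        assert double.lower_percentile == pytest.approx(0.0392070, abs=1e-6)
        assert double.upper_percentile == pytest.approx(0.9846123, abs=1e-6)
        assert single.lower_percentile == pytest.approx(0.0314453, abs=1e-6)

    def test_positive_bias_shifts_percentiles_upward_in_order(self):
        dist = random_dist(3, ab_quantile=0.6)
        p, r, b = pbci(dist), rbcbci(dist), bcbci(dist)
        assert b.z_adj_hat > 0
        assert p.lower_percentile < r.lower_percentile < b.lower_percentile
        assert p.upper_percentile < r.upper_percentile < b.upper_percentile


class TestSignificanceTestedInterval:
    def test_gate_thresholds_reproduce_published_cutoffs(self):
        lo, hi = gate_thresholds(5000, 0.05)
        assert (round(lo, 4), round(hi, 4)) == (0.4862, 0.5138)

    def test_exact_gate_agrees_at_default_settings(self):
        assert gate_thresholds(5000, 0.05, exact=True) == gate_thresholds(5000, 0.05)

    def test_median_estimate_takes_percentile_branch(self):
        dist = random_dist(1, ab_quantile=0.5)
        ci = stbcbci(dist)
        p = pbci(dist)
        assert ci.branch == "percentile"
        assert (ci.lower, ci.upper) == (p.lower, p.upper)

    def test_proportion_052_takes_bias_corrected_branch(self):
        dist = make_dist(np.arange(1.0, 5001.0), source_ab_hat=2600.5)
        ci = stbcbci(dist)  # proportion 0.52 > 0.5138
        b = bcbci(dist)
        assert ci.branch == "bias_corrected"
        assert (ci.lower, ci.upper) == (b.lower, b.upper)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 1000), q=st.floats(0.01, 0.99))
    def test_always_bit_identical_to_bc_or_percentile(self, seed, q):
        dist = random_dist(seed, B=200, ab_quantile=q)
        ci = stbcbci(dist)
        p, b = pbci(dist), bcbci(dist)
        assert (ci.lower, ci.upper) in {(p.lower, p.upper), (b.lower, b.upper)}


class TestWinsorizedInterval:
    def test_hand_enumerated_winsorized_mean(self):
        assert winsorized_mean(np.arange(1.0, 11.0), 0.30) == 5.5

    def test_gamma_zero_is_arithmetic_mean(self):
        v = np.array([3.0, 1.0, 7.0, 5.0])
        assert winsorized_mean(v, 0.0) == pytest.approx(v.mean())

    def test_symmetric_values_unchanged_by_any_gamma(self):
        v = np.arange(-6.0, 7.0)
        for g in (0.1, 0.25, 0.4, 0.5):
            assert winsorized_mean(v, g) == pytest.approx(0.0)

    @pytest.mark.parametrize("g", [-0.1, 0.6])
    def test_gamma_out_of_range_rejected(self, g):
        with pytest.raises(ValueError, match="gamma"):
            winsorized_mean(np.arange(5.0), g)

    def test_half_winsorization_recovers_percentile_interval(self):
        dist = random_dist(4, ab_quantile=0.7)
        ci = wbcbci(dist, CIRequest(gamma=0.5))
        p = pbci(dist)
        assert ci.z_adj_hat == 0.0
        assert (ci.lower, ci.upper) == (p.lower, p.upper)

    def test_symmetric_distribution_centered_at_estimate_matches_bc_and_p(self):
        # even count, symmetric about 0, estimate exactly at the median
        est = np.concatenate([np.arange(-100.0, 0.0), np.arange(1.0, 101.0)])
        dist = make_dist(est, source_ab_hat=0.0)
        w, b, p = wbcbci(dist), bcbci(dist), pbci(dist)
        assert (w.lower, w.upper) == (b.lower, b.upper) == (p.lower, p.upper)


class TestRequestValidation:
    @pytest.mark.parametrize(
        "kwargs", [{"level": 0.0}, {"level": 1.0}, {"alpha_test": 0.0}, {"gamma": 0.7}]
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CIRequest(**kwargs)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(seed=st.integers(0, 500), q=st.floats(0.05, 0.95))
def test_intervals_nest_across_confidence_levels(seed, q):
    dist = random_dist(seed, B=300, ab_quantile=q)
    for fn in (pbci, bcbci, rbcbci, wbcbci, stbcbci):
        last = None
        for level in (0.80, 0.90, 0.95):
            if fn is wbcbci:
                ci = fn(dist, CIRequest(level=level))
            else:
                ci = fn(dist, req=CIRequest(level=level))
            if last is not None:
                assert ci.lower <= last.lower and ci.upper >= last.upper
            last = ci


@settings(deadline=None, max_examples=40, derandomize=True)
@given(seed=st.integers(0, 500), q=st.floats(0.05, 0.95))
def test_all_limits_are_order_statistics_of_the_distribution(seed, q):
    dist = random_dist(seed, B=150, ab_quantile=q)
    values = set(dist.estimates.tolist())
    for fn in (pbci, bcbci, rbcbci, wbcbci, stbcbci):
        ci = fn(dist) if fn in (pbci, wbcbci) else fn(dist, None, CIRequest())
        assert ci.lower in values and ci.upper in values
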