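"""MSS pmf, likelihood, MLE and confidence intervals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluctassay.fluctuation import (
    confidence_interval,
    estimate_m,
    mss_log_likelihood,
    mss_pmf,
)


class TestMssPmf:
    def test_zero_class_is_poisson(self):
        # p0 = exp(-m): no mutation event in the culture
        assert mss_pmf(1.0, 0)[0] == pytest.approx(math.exp(-1), abs=1e-12)

    def test_first_recursion_step_by_hand(self):
        # p1 = (m/1) * p0 / 2 at m=1: exp(-1)/2
        p = mss_pmf(1.0, 1)
        assert p[1] == pytest.approx(math.exp(-1) / 2, abs=1e-12)

    def test_m_zero_is_point_mass(self):
        p = mss_pmf(0.0, 5)
        assert p[0] == 1.0
        assert np.all(p[1:] == 0.0)

    def test_rejects_negative_m(self):
        with pytest.raises(ValueError):
            mss_pmf(-0.1, 5)

    @settings(deadline=None, max_examples=25)
    @given(st.floats(min_value=0.01, max_value=10.0))
    def test_valid_probability_vector(self, m):
        p = mss_pmf(m, 400)
        assert np.all(p >= 0.0)
        assert np.all(p <= 1.0)
        # mass within [0, k_max] plus a tail bounded by the heavy-tail rate:
        # P(K > k) ~ m/k for the Luria-Delbruck law
        assert p.sum() <= 1.0 + 1e-12
        assert 1.0 - p.sum() < 2.5 * m / 400

    def test_matches_compound_poisson_construction(self):
        # Independent oracle: the LD distribution is compound Poisson with
        # clone-size law q_j = 1/(j(j+1)); build the pmf by direct
        # convolution of Poisson-many clones, truncated at k_max.
        m, k_max = 1.5, 60
        q = np.zeros(k_max + 1)
        j = np.arange(1, k_max + 1)
        q[1:] = 1.0 / (j * (j + 1))
        weight = math.exp(-m)
        out = np.zeros(k_max + 1)
        out[0] = weight
        conv = np.zeros(k_max + 1)
        conv[0] = 1.0
        for n_clones in range(1, 200):
            conv = np.convolve(conv, q)[: k_max + 1]
            weight = weight * m / n_clones
            out += weight * conv
            if weight < 1e-18:
                break
        assert np.allclose(mss_pmf(m, k_max), out, atol=1e-10)


class TestLogLikelihood:
    def test_all_zero_counts(self):
        assert mss_log_likelihood(1.0, [0, 0, 0]) == pytest.approx(-3.0, abs=1e-12)

    def test_sum_of_log_pmf(self):
        expected = math.log(math.exp(-1)) + math.log(math.exp(-1) / 2)
        assert mss_log_likelihood(1.0, [0, 1]) == pytest.approx(expected, abs=1e-12)

    def test_m_zero_with_mutants_is_impossible(self):
        assert mss_log_likelihood(0.0, [0, 2]) == -math.inf
        assert mss_log_likelihood(0.0, [0, 0]) == 0.0

    def test_tail_pooling_keeps_likelihood_proper(self):
        # a jackpot count beyond k_cap contributes the tail mass
        ll = mss_log_likelihood(2.0, [0, 1, 10_000], k_cap=50)
        p = mss_pmf(2.0, 50)
        expected = math.log(p[0]) + math.log(p[1]) + math.log(1 - p.sum())
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_all_zero_maximized_at_boundary(self):
        lls = [mss_log_likelihood(m, [0] * 12) for m in (0.0, 0.01, 0.1, 1.0)]
        assert lls == sorted(lls, reverse=True)


class TestEstimateM:
    def test_all_zero_returns_boundary(self):
        est = estimate_m([0] * 12)
        assert est.m_hat == 0.0
        assert est.boundary
        assert est.n_cultures == 12

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_m([])

    def test_self_consistency_at_large_n(self):
        # counts drawn from the pmf itself: m_hat within 2% of truth
        rng = np.random.default_rng(17)
        m_true, k_max = 2.0, 2000
        p = mss_pmf(m_true, k_max)
        counts = rng.choice(np.arange(k_max + 1), size=10_000, p=p / p.sum())
        est = estimate_m(counts)
        assert est.m_hat == pytest.approx(m_true, rel=0.02)

    def test_toy_counts_match_grid_search(self, toy_counts):
        est = estimate_m(toy_counts)
        grid = np.arange(1e-4, 3.0, 1e-4)
        lls = np.array([mss_log_likelihood(m, toy_counts) for m in grid])
        assert est.m_hat == pytest.approx(grid[lls.argmax()], abs=2e-4)

    def test_more_mutants_means_larger_m(self, toy_counts):
        # doubling every count moves the estimate upward
        m1 = estimate_m(toy_counts).m_hat
        m2 = estimate_m(2 * toy_counts).m_hat
        assert m2 > m1


class TestConfidenceInterval:
    def test_profile_contains_mle(self, toy_counts):
        est = estimate_m(toy_counts)
        lo, hi = confidence_interval(est.m_hat, toy_counts, "profile_likelihood")
        assert lo <= est.m_hat <= hi

    def test_stewart_closed_form(self, toy_counts):
        est = estimate_m(toy_counts)
        lo, hi = confidence_interval(est.m_hat, toy_counts, "stewart", level=0.95)
        sigma = 1.225 * est.m_hat**-0.315 / math.sqrt(len(toy_counts))
        assert lo == pytest.approx(est.m_hat * math.exp(-1.959964 * sigma), rel=1e-5)
        assert hi == pytest.approx(est.m_hat * math.exp(1.959964 * sigma), rel=1e-5)

    def test_boundary_returns_degenerate_interval(self):
        lo, hi = confidence_interval(0.0, [0] * 10, "stewart")
        assert lo == 0.0
        assert hi > 0.0

    def test_methods_agree_asymptotically(self):
        # on a 1000-culture dataset the two intervals nearly coincide
        rng = np.random.default_rng(3)
        p = mss_pmf(2.0, 2000)
        counts = rng.choice(np.arange(2001), size=1000, p=p / p.sum())
        est = estimate_m(counts)
        s = confidence_interval(est.m_hat, counts, "stewart")
        q = confidence_interval(est.m_hat, counts, "profile_likelihood")
        width_s, width_q = s[1] - s[0], q[1] - q[0]
        assert abs(width_s - width_q) / width_q < 0.10

    def test_unknown_method_rejected(self, toy_counts):
        with pytest.raises(ValueError):
            confidence_interval(1.0, toy_counts, "bootstrap")
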