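"""Closed-form expectations, steady states and exact chain oracles."""

import math

import numpy as np
import pytest

from borderindel import (
    IndelLengthDistribution,
    IndelModelParams,
    chain_stationary_pmf,
    generations_to_stationarity,
    m1_expectation,
    m1_stationary_mean,
    m1_stationary_pmf,
    m1_trajectory,
    m2_expectation,
    m2_stationary_mean,
)


class TestM1Expectation:
    def test_generation_zero_returns_initial_length(self):
        assert m1_expectation(0, L0=5.0, p_ins=0.003, p_del=0.007) == 5.0

    def test_equal_rates_grow_linearly(self):
        assert m1_expectation(100, L0=0.0, p_ins=0.01, p_del=0.01) == \
            pytest.approx(1.0)

    def test_deletion_bias_converges_to_ratio_limit(self):
        # r = 0.9 -> L_inf = 0.009 / 0.001 = 9
        val = m1_expectation(10_000_000, L0=0.0, p_ins=0.009, p_del=0.01)
        assert val == pytest.approx(9.0, rel=1e-9)

    def test_three_growth_regimes(self):
        n = np.arange(0, 2001)
        growing = m1_expectation(n, 0.0, 0.0105, 0.01)
        linear = m1_expectation(n, 0.0, 0.01, 0.01)
        decaying = m1_expectation(n, 100.0, 0.009, 0.01)
        assert np.all(np.diff(growing) > 0)
        assert np.diff(growing)[-1] > np.diff(growing)[0]  # accelerating
        assert np.allclose(np.diff(linear), 0.01)
        assert np.all(np.diff(decaying) < 0)
        assert decaying[-1] > 9.0  # decays toward, never below, L_inf

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            m1_expectation(1, 0.0, -0.01, 0.01)


class TestStationaryMeans:
    @pytest.mark.parametrize("r,expected", [(0.9, 9.0), (0.99, 99.0),
                                            (0.999, 999.0), (0.0, 0.0)])
    def test_m1_steady_state(self, r, expected):
        assert m1_stationary_mean(r) == pytest.approx(expected)

    def test_m1_divergence_signalled(self):
        with pytest.raises(ValueError):
            m1_stationary_mean(1.0)

    def test_m2_reduces_to_m1_at_unit_deletions(self):
        for r in (0.2, 0.9, 0.999):
            assert m2_stationary_mean(r, mu_d=1) == \
                pytest.approx(m1_stationary_mean(r))

    def test_m2_direct_value(self):
        assert m2_stationary_mean(0.99, mu_d=5) == pytest.approx(499.0)

    def test_m2_is_mu_d_fold_m1_near_critical_ratio(self):
        r = 1 - 1e-9
        for mu_d in (2, 5, 15):
            ratio = m2_stationary_mean(r, mu_d) / m1_stationary_mean(r)
            assert ratio == pytest.approx(mu_d, rel=1e-6)


class TestM2Expectation:
    def test_generation_zero(self):
        assert m2_expectation(0, L0=3.0, r=0.5, p_del=1e-3, mu_d=5) == 3.0

    def test_unit_lengths_match_m1_trajectory(self):
        n = np.arange(0, 500)
        p_del = 1e-3
        r = 0.7
        via_m2 = m2_expectation(n, 0.0, r, p_del, mu_d=1)
        via_m1 = m1_expectation(n, 0.0, r * p_del, p_del)
        assert np.allclose(via_m2, via_m1)

    def test_limit_reaches_steady_state(self):
        val = m2_expectation(10_000_000, 0.0, r=0.99, p_del=1e-3, mu_d=5)
        assert val == pytest.approx(499.0, rel=1e-6)


class TestConvergenceHorizon:
    def test_trivial_tolerance_needs_no_generations(self):
        assert generations_to_stationarity(0.5, 1e-3, 5, epsilon=1.0) == 0

    @pytest.mark.parametrize("r,p_del,mu_d", [(0.25, 1e-8, 15),
                                              (0.983, 1e-7, 4.5)])
    def test_matches_direct_formula(self, r, p_del, mu_d):
        # oracle: direct evaluation of the transient-factor inequality
        expected = math.ceil(math.log(1e-6) /
                             math.log1p(-(1 - r) * p_del * mu_d))
        got = generations_to_stationarity(r, p_del, mu_d, 1e-6)
        assert got == expected
        # bracketing property, evaluated in log space to keep precision
        log_factor = math.log1p((r - 1) * p_del * mu_d)
        assert got * log_factor < math.log(1e-6) <= (got - 1) * log_factor

    def test_divergent_ratio_rejected(self):
        with pytest.raises(ValueError):
            generations_to_stationarity(1.0, 1e-3, 5)


class TestM1StationaryPmf:
    def test_zero_ratio_is_point_mass_at_zero(self):
        pmf = m1_stationary_pmf(0.0, 10)
        assert pmf[0] == 1.0 and pmf[1:].sum() == 0.0

    def test_untruncated_mean_matches_closed_form(self):
        # geometric on {0,1,...} with success 1-r has mean r/(1-r)
        pmf = m1_stationary_pmf(0.9, 400)  # truncation mass ~r^401, negligible
        mean = (pmf * np.arange(401)).sum()
        assert mean == pytest.approx(m1_stationary_mean(0.9), rel=1e-8)

    def test_matches_explicit_transition_matrix(self):
        # independent oracle: dense one-generation birth-death matrix,
        # stationary vector by linear solve
        r, p_del, n_max = 0.5, 0.3, 30
        p_ins = r * p_del
        N = n_max + 1
        P = np.zeros((N, N))
        for L in range(N):
            up = p_ins * (L + 1)
            down = p_del * L
            P[L, min(L + 1, n_max)] += up
            if L >= 1:
                P[L, L - 1] += down
            P[L, L] += 1 - up - down
        A = P.T - np.eye(N)
        A[-1, :] = 1.0
        b = np.zeros(N)
        b[-1] = 1.0
        stat = np.linalg.solve(A, b)
        assert np.abs(stat - m1_stationary_pmf(r, n_max)).max() < 1e-10


class TestChainOracle:
    def test_no_insertions_collapse_to_zero(self):
        params = IndelModelParams(
            p_ins=0.0, p_del=1e-3,
            ins_dist=IndelLengthDistribution.constant(1),
            del_dist=IndelLengthDistribution.constant(1))
        pmf = chain_stationary_pmf(params, 50)
        assert pmf[0] == pytest.approx(1.0, abs=1e-12)

    def test_unit_lengths_reproduce_geometric_law(self):
        params = IndelModelParams.m1(0.5, 1e-3)
        pmf = chain_stationary_pmf(params, 60)
        tv = 0.5 * np.abs(pmf - m1_stationary_pmf(0.5, 60)).sum()
        assert tv < 1e-8

    def test_rate_rescaling_leaves_stationary_law_unchanged(self):
        base = IndelModelParams(
            p_ins=7.5e-9, p_del=1e-8,
            ins_dist=IndelLengthDistribution.zipf(mean=5),
            del_dist=IndelLengthDistribution.zipf(mean=15))
        scaled = IndelModelParams(
            p_ins=7.5e-5, p_del=1e-4,
            ins_dist=base.ins_dist, del_dist=base.del_dist)
        a = chain_stationary_pmf(base, 300)
        b = chain_stationary_pmf(scaled, 300)
        assert 0.5 * np.abs(a - b).sum() < 1e-6


def test_m1_trajectory_container():
    traj = m1_trajectory(100, L0=0.0, p_ins=0.009, p_del=0.01)
    assert traj.values[0] == 0.0
    assert traj.L_inf == pytest.approx(9.0)
    assert np.all(np.diff(traj.values) > 0)
    assert traj.values[-1] < traj.L_inf
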