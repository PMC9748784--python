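"""Stochastic simulator: deletion validity, stationary laws, invariances."""

import numpy as np
import pytest
from scipy.stats import chisquare, ks_2samp

from borderindel import (
    IndelLengthDistribution,
    IndelModelParams,
    SimulationConfig,
    chain_stationary_pmf,
    m1_stationary_mean,
    m1_stationary_pmf,
    p_valid,
    simulate_stationary,
    summarize,
)


class TestPValid:
    def test_unit_deletion_always_fits(self):
        assert p_valid(3, 1) == 1.0

    def test_deletion_longer_than_sequence_is_impossible(self):
        assert p_valid(3, 5) == 0.0

    def test_anchored_placement_count(self):
        assert p_valid(10, 4) == pytest.approx(0.7)  # (10-4+1)/10

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            p_valid(0, 1)


class TestAbsorbingAndDegenerate:
    def test_no_insertions_from_zero_stay_zero(self):
        params = IndelModelParams(
            p_ins=0.0, p_del=1e-3,
            ins_dist=IndelLengthDistribution.constant(1),
            del_dist=IndelLengthDistribution.constant(1))
        s = simulate_stationary(params, SimulationConfig(n_replicates=200, seed=4))
        assert np.all(s.lengths == 0)

    def test_no_events_at_all_keep_initial_length(self):
        params = IndelModelParams(
            p_ins=0.0, p_del=0.0,
            ins_dist=IndelLengthDistribution.constant(1),
            del_dist=IndelLengthDistribution.constant(1))
        s = simulate_stationary(params,
                                SimulationConfig(n_replicates=10, L0=7, seed=0))
        assert np.all(s.lengths == 7)

    def test_insertion_bias_raises(self):
        params = IndelModelParams.m1(1.5, 1e-3)
        with pytest.raises(ValueError):
            simulate_stationary(params, SimulationConfig(n_replicates=10, seed=0))

    def test_m2_with_unit_lengths_is_exactly_m1(self):
        cfg = SimulationConfig(n_replicates=2000, seed=5)
        a = simulate_stationary(IndelModelParams.m1(0.6, 1e-3), cfg)
        b = simulate_stationary(IndelModelParams.m2(0.6, 1e-3, 1, 1), cfg)
        assert np.array_equal(a.lengths, b.lengths)


class TestM1StationaryLaw:
    def test_geometric_law_by_chi_square(self):
        """The M1 stationary distribution is geometric(1 - r) on {0,1,...}."""
        r = 0.5
        cfg = SimulationConfig(n_replicates=10_000, seed=6)
        s = simulate_stationary(IndelModelParams.m1(r, 0.01), cfg)
        n_max = 40
        counts = np.bincount(np.minimum(s.lengths, n_max), minlength=n_max + 1)
        expected = m1_stationary_pmf(r, 400)
        exp_binned = np.append(expected[:n_max],
                               expected[n_max:].sum()) * cfg.n_replicates
        keep = exp_binned >= 5
        obs = np.append(counts[keep], counts[~keep].sum())
        exp = np.append(exp_binned[keep], exp_binned[~keep].sum())
        stat, pval = chisquare(obs, exp * obs.sum() / exp.sum())
        assert pval > 0.001

    @pytest.mark.parametrize("r,n_rep", [(0.5, 5000), (0.9, 3000), (0.99, 800)])
    def test_mean_matches_closed_form(self, r, n_rep):
        # p_del=1e-4 keeps p_event(L) far below 1 across the geometric tail
        cfg = SimulationConfig(n_replicates=n_rep, seed=7)
        s = simulate_stationary(IndelModelParams.m1(r, 1e-4), cfg)
        se = s.lengths.std(ddof=1) / np.sqrt(n_rep)
        assert abs(s.lengths.mean() - m1_stationary_mean(r)) < 3 * se


class TestM3Properties:
    def test_matches_exact_chain_in_total_variation(self):
        """Simulated stationary law vs the exact truncated-chain oracle, on a
        narrow-support parameter set where 10 000 replicates resolve the
        distribution to well below the tolerance."""
        params = IndelModelParams.m3(0.25, 1e-5, 1.5, 4)
        cfg = SimulationConfig(n_replicates=10_000, seed=14)
        sample = simulate_stationary(params, cfg)
        L_max = 300
        oracle = chain_stationary_pmf(params, L_max)
        lengths = np.minimum(sample.lengths, L_max)
        emp = np.bincount(lengths, minlength=L_max + 1) / lengths.size
        tv = 0.5 * np.abs(emp - oracle).sum()
        assert tv < 0.03

    def test_strong_bias_mean_matches_exact_chain(self, strong_bias_params,
                                                  strong_bias_sample):
        """In the rejection-dominated regime the simulated mean agrees with
        the exact chain solve (the analytic M2 bound badly underestimates it)."""
        oracle = chain_stationary_pmf(strong_bias_params, 600)
        oracle_mean = (oracle * np.arange(601)).sum()
        se = strong_bias_sample.lengths.std(ddof=1) / 100.0
        assert abs(strong_bias_sample.lengths.mean() - oracle_mean) < 3 * se

    def test_short_sequence_insertion_bias_keeps_mean_above_mu_d(
            self, strong_bias_sample):
        """Even at r = 0.25 with mean deletions of 15 bp, rejection of
        protruding deletions keeps the stationary mean above mu_d."""
        assert strong_bias_sample.lengths.mean() > 15.0

    def test_rate_rescaling_invariance(self):
        """Jointly scaling (p_ins, p_del) by 0.1x or 10x changes only the
        time scale, not the stationary distribution."""
        ins = IndelLengthDistribution.zipf(mean=5)
        dele = IndelLengthDistribution.zipf(mean=15)
        samples = {}
        for c in (0.1, 1.0, 10.0):
            params = IndelModelParams(p_ins=7.5e-6 * c, p_del=1e-5 * c,
                                      ins_dist=ins, del_dist=dele)
            cfg = SimulationConfig(n_replicates=5000, seed=8)
            samples[c] = simulate_stationary(params, cfg).lengths
        for c in (0.1, 10.0):
            stat, pval = ks_2samp(samples[1.0], samples[c])
            assert pval > 0.001


class TestDeterminismAndSummary:
    def test_identical_seed_identical_sample(self):
        params = IndelModelParams.m3(0.25, 1e-5, 5, 15)
        cfg = SimulationConfig(n_replicates=500, seed=9)
        a = simulate_stationary(params, cfg)
        b = simulate_stationary(params, cfg)
        assert np.array_equal(a.lengths, b.lengths)
        c = simulate_stationary(params,
                                SimulationConfig(n_replicates=500, seed=10))
        assert not np.array_equal(a.lengths, c.lengths)

    def test_summary_of_constant_sample(self):
        params = IndelModelParams(
            p_ins=0.0, p_del=0.0,
            ins_dist=IndelLengthDistribution.constant(1),
            del_dist=IndelLengthDistribution.constant(1))
        s = simulate_stationary(params,
                                SimulationConfig(n_replicates=50, L0=7, seed=0))
        summ = summarize(s)
        assert summ.mean == 7.0 and summ.sd == 0.0
        assert summ.min == summ.max == 7.0
        # mode bin must contain log10(7)
        assert abs(summ.mode_log10 - np.log10(7)) <= 0.025 + 1e-12

    def test_summary_counts_zero_lengths(self, strong_bias_sample):
        summ = summarize(strong_bias_sample)
        assert summ.n_zero == int(np.sum(strong_bias_sample.lengths == 0))
        assert summ.n == 10_000

    def test_geometric_sample_summary_against_closed_form(self):
        """Summary statistics of an M1 run agree with the geometric law."""
        r = 0.9
        cfg = SimulationConfig(n_replicates=3000, seed=12)
        s = simulate_stationary(IndelModelParams.m1(r, 1e-3), cfg)
        summ = summarize(s)
        mean_true = r / (1 - r)
        sd_true = np.sqrt(r) / (1 - r)
        se = sd_true / np.sqrt(cfg.n_replicates)
        assert abs(summ.mean - mean_true) < 3 * se
        assert summ.sd == pytest.approx(sd_true, rel=0.1)
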