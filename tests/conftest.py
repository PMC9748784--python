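import numpy as np
import pytest

from borderindel import (
    IndelLengthDistribution,
    IndelModelParams,
    SimulationConfig,
    simulate_stationary,
)


@pytest.fixture(scope="session")
def strong_bias_params():
    """M3 in the strong deletion-bias regime (r = 0.25): insertions are rare
    and short, deletions common and long, yet border-induced rejection keeps
    sequences alive."""
    return IndelModelParams(
        p_ins=7.5e-9, p_del=1e-8,
        ins_dist=IndelLengthDistribution.zipf(mean=5),
        del_dist=IndelLengthDistribution.zipf(mean=15),
    )


@pytest.fixture(scope="session")
def strong_bias_sample(strong_bias_params):
    """10 000 stationary draws from the strong deletion-bias regime."""
    cfg = SimulationConfig(n_replicates=10_000, seed=20_202)
    return simulate_stationary(strong_bias_params, cfg)


@pytest.fixture(scope="session")
def human_fit_m3_params():
    """M3 at the ratio fitted to human introns with conserved segments
    accounted for (r = 0.9776, mean indel lengths 16.5/4.5 bp)."""
    return IndelModelParams.m3(0.9776, 1e-7, 16.5, 4.5)


@pytest.fixture(scope="session")
def human_fit_m3_sample(human_fit_m3_params):
    """2 500 stationary draws at the human-fitted M3 base parameters.

    Expensive (about a minute); shared by the conserved-edge bimodality
    check and the mixture-mean reproduction checks.
    """
    cfg = SimulationConfig(n_replicates=2500, seed=40_404)
    return simulate_stationary(human_fit_m3_params, cfg)
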