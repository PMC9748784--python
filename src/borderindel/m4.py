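"""M4: the conserved-segment mixture on top of the M3 length process.

An intron is modelled as conserved edge sequence of total length ``le``
(the 5' and 3' splice sites) plus neutral material.  With probability ``pc``
it additionally carries a single internal conserved segment of length
``li``; that segment splits the neutral material into two independent
stretches, each evolving as a full M3 process with its own conserved
borders.  Intron length is therefore

    le + X1                 with probability 1 - pc,
    le + li + X1 + X2       with probability pc,

where X1, X2 are independent stationary M3 draws.  The mixture mean is
exactly ``le + pc*li + (1 + pc) * E[X]``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .simulator import IndelModelParams, SimulationConfig, StationarySample, \
    simulate_stationary

__all__ = ["M4Params", "simulate_m4", "mixture_mean"]


@dataclass
class M4Params:
    """Conserved-segment parameters, shared by all simulated introns.

    ``le`` and ``li`` are lengths in bp; biologically they are integers, but
    nonnegative reals are accepted so the fitting routine can optimize them
    continuously.
    """

    le: float = 0.0
    li: float = 0.0
    pc: float = 0.0

    def __post_init__(self):
        if self.le < 0 or self.li < 0:
            raise ValueError("conserved lengths le, li must be nonnegative")
        if not (0.0 <= self.pc <= 1.0):
            raise ValueError(f"pc must lie in [0, 1], got {self.pc}")


def _derived_seed(seed: int, salt: int) -> int:
    return (seed * 2_654_435_761 + salt) % (2**31 - 1)


def simulate_m4(m3_params: IndelModelParams, m4_params: M4Params,
                config: SimulationConfig) -> StationarySample:
    """Draw ``config.n_replicates`` intron lengths from the M4 mixture.

    A single reservoir of stationary M3 draws is simulated (one per
    replicate plus one extra per internal-segment success) and assembled
    into the mixture; each draw is used exactly once, so the two stretches
    of a split intron are independent full-rate M3 processes.

    Lengths are floats (``le``/``li`` may be non-integer during fitting).
    """
    n = config.n_replicates
    rng = np.random.default_rng(_derived_seed(config.seed, 0x4D34))
    # stratified mixture flags: a fixed random permutation of the grid
    # (i + 0.5)/n thresholded at pc.  The internal-segment fraction is then
    # exactly pc to within 1/n and varies smoothly with pc, which removes
    # Bernoulli noise from the mixture weight (important when pc is being
    # optimized against a stochastic objective).
    strata = (rng.permutation(n) + 0.5) / n
    has_internal = strata < m4_params.pc
    n_draws = int(n + has_internal.sum())
    inner_cfg = replace(config, n_replicates=n_draws,
                        seed=_derived_seed(config.seed, 0x4D35))
    reservoir = simulate_stationary(m3_params, inner_cfg)
    draws = reservoir.lengths.astype(float)
    lengths = m4_params.le + draws[:n]
    lengths[has_internal] += m4_params.li + draws[n:]
    return StationarySample(lengths=lengths, params_used=m3_params,
                            generations_run=reservoir.generations_run,
                            config=config)


def mixture_mean(m4_params: M4Params, m3_mean: float) -> float:
    """Exact mixture mean ``le + pc*li + (1 + pc) * m3_mean``."""
    return m4_params.le + m4_params.pc * m4_params.li \
        + (1.0 + m4_params.pc) * m3_mean
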