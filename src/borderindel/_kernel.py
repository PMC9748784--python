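"""Numba kernel for the discrete-generation Gillespie length simulator.

Waiting times between indel events are geometric with per-generation success
probability ``p_event(L) = p_ins*(L+1) + p_del*L``, so run time scales with
the number of events rather than the number of generations (horizons at
fitted parameters are ~1e9 generations but only ~1e5 events).

Each replicate owns an independent splitmix64 stream seeded from a
SeedSequence-derived 64-bit word, which keeps runs reproducible and
replicates independent without the overhead of a heavyweight generator.
"""

import math

import numpy as np
from numba import njit

# replicate status codes
OK = 0
HIT_CAP = 1
P_EVENT_OVERFLOW = 2

_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, fastmath=True, inline="always")
def _rand01(state):
    """splitmix64 step: returns (new_state, uniform double in [0, 1))."""
    state = state + _GAMMA
    z = state
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    z = z ^ (z >> np.uint64(31))
    return state, float(z >> np.uint64(11)) * _INV53


@njit(cache=True, fastmath=True, inline="always")
def _pick_length(cdf, u):
    """Inverse-CDF lookup: smallest k with cdf[k-1] > u, as a length 1..len(cdf)."""
    lo = 0
    hi = cdf.shape[0] - 1
    while lo < hi:
        mid = (lo + hi) >> 1
        if cdf[mid] > u:
            hi = mid
        else:
            lo = mid + 1
    return lo + 1


@njit(cache=True, fastmath=True)
def run_replicates(seeds, L_init, horizon, p_ins, p_del, ins_cdf, del_cdf,
                   L_cap):
    """Advance each replicate ``horizon`` generations from its initial length.

    ``L_init`` holds one starting length per replicate, so a sample can be
    continued by feeding its final lengths back in with fresh seeds.
    """
    n_rep = seeds.shape[0]
    out = np.empty(n_rep, dtype=np.int64)
    status = np.zeros(n_rep, dtype=np.int64)
    for j in range(n_rep):
        state = seeds[j]
        L = L_init[j]
        gen = np.int64(0)
        while True:
            p_event = p_ins * (L + 1) + p_del * L
            if p_event <= 0.0:
                break  # absorbing: no insertions possible and length 0
            if p_event >= 1.0:
                status[j] = P_EVENT_OVERFLOW
                break
            # geometric waiting time (support {1, 2, ...})
            state, u = _rand01(state)
            wait = np.int64(math.ceil(math.log1p(-u) / math.log1p(-p_event)))
            if wait < 1:
                wait = np.int64(1)
            gen += wait
            if gen > horizon:
                break
            p_ins_total = p_ins * (L + 1)
            state, u = _rand01(state)
            u *= p_event
            if u < p_ins_total:
                # insertion: always applies; reuse u for the length lookup
                k = _pick_length(ins_cdf, u / p_ins_total)
                L += k
                if L > L_cap:
                    status[j] = HIT_CAP
                    break
            else:
                # deletion: applies only if it fits inside the neutral
                # stretch; otherwise a null event (the waiting time is spent)
                k = _pick_length(
                    del_cdf, (u - p_ins_total) / (p_event - p_ins_total))
                p_valid = (L - k + 1.0) / L
                state, v = _rand01(state)
                if p_valid > 0.0 and v < p_valid:
                    L -= k
        out[j] = L
    return out, status
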