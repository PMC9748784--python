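"""Closed-form results for the unit-indel (M1) and fixed-size (M2) models,
plus exact stationary-distribution oracles on truncated state spaces.

The length of a neutral sequence flanked by conserved regions evolves as a
birth-death chain: insertions arrive at per-generation probability
``p_ins * (L + 1)`` (there is one more insertion site than characters — the
immortal-link construction), deletions at ``p_del * L``.  With unit indels
(M1) the expectation obeys a linear difference equation whose fixed point is

    L_inf = r / (1 - r),        r = p_ins / p_del,

and the stationary law is geometric.  With fixed indel sizes mu_i / mu_d
(M2), away from the short-length boundary the fixed point becomes

    L_inf = (r + mu_d - 1) / (1 - r),    r = (p_ins mu_i) / (p_del mu_d),

which is a lower bound on the true stationary mean when the deletion bias is
strong (border-induced rejection of protruding deletions inflates short
sequences).  The oracles at the bottom of this module compute stationary
vectors of the exact truncated chain and are used to verify the stochastic
simulator.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

__all__ = [
    "m1_expectation",
    "m1_stationary_mean",
    "m2_expectation",
    "m2_stationary_mean",
    "generations_to_stationarity",
    "m1_stationary_pmf",
    "chain_stationary_pmf",
    "ExpectationTrajectory",
    "m1_trajectory",
    "m2_trajectory",
]


from dataclasses import dataclass


@dataclass
class ExpectationTrajectory:
    """Expected length through generations, with its limit.

    ``values[k]`` is the expected length at generation ``k``; ``L_inf`` is
    ``+inf`` when the insertion bias makes the expectation diverge.
    """

    values: np.ndarray
    L0: float
    L_inf: float


def m1_expectation(n, L0: float, p_ins: float, p_del: float):
    """Expected length at generation ``n`` under unit indels (M1).

    Equal rates give linear growth ``L0 + n*p_ins``; otherwise
    ``(L0 - L_inf)(1 + p_ins - p_del)^n + L_inf`` with
    ``L_inf = p_ins / (p_del - p_ins)`` (negative — i.e. divergent — when
    insertions dominate).
    """
    if p_ins < 0 or p_del < 0:
        raise ValueError("insertion/deletion probabilities must be nonnegative")
    n = np.asarray(n, dtype=float)
    if p_ins == p_del:
        out = L0 + n * p_ins
    else:
        L_inf = p_ins / (p_del - p_ins)
        out = (L0 - L_inf) * (1.0 + p_ins - p_del) ** n + L_inf
    return float(out) if out.ndim == 0 else out


def m1_stationary_mean(r: float) -> float:
    """Steady-state expected length ``r / (1 - r)`` of M1, for ``0 <= r < 1``."""
    if r < 0:
        raise ValueError(f"r must be nonnegative, got {r}")
    if r >= 1:
        raise ValueError(f"no stationary mean: insertion bias r={r} >= 1")
    return r / (1.0 - r)


def m2_stationary_mean(r: float, mu_d: float) -> float:
    """Steady-state expected length ``(r + mu_d - 1) / (1 - r)`` of M2.

    Exact in the regime ``L_inf >> mu_d``; a lower bound under strong
    deletion bias (``r`` near 0), where border-induced rejection of large
    deletions keeps sequences longer than the formula predicts.
    """
    if r < 0:
        raise ValueError(f"r must be nonnegative, got {r}")
    if mu_d < 1:
        raise ValueError(f"mean deletion length must be >= 1, got {mu_d}")
    if r >= 1:
        raise ValueError(f"no stationary mean: insertion bias r={r} >= 1")
    return (r + mu_d - 1.0) / (1.0 - r)


def m2_expectation(n, L0: float, r: float, p_del: float, mu_d: float):
    """Expected length at generation ``n`` under fixed-size indels (M2).

    ``(L0 - L_inf)(1 + (r-1) p_del mu_d)^n + L_inf``; valid in the
    ``L_inf >> mu_d`` regime where the short-length boundary is negligible.
    """
    if p_del < 0:
        raise ValueError("p_del must be nonnegative")
    L_inf = m2_stationary_mean(r, mu_d)
    n = np.asarray(n, dtype=float)
    out = (L0 - L_inf) * (1.0 + (r - 1.0) * p_del * mu_d) ** n + L_inf
    return float(out) if out.ndim == 0 else out


def generations_to_stationarity(r: float, p_del: float, mu_d: float,
                                epsilon: float = 1e-6) -> int:
    """Smallest ``n`` with transient factor ``(1 + (r-1) p_del mu_d)^n < epsilon``.

    This is the convergence horizon used by the stochastic simulator; the
    same factor governs M1 (``mu_d = 1``), M2 and — with ``mu_d`` the mean
    of the deletion-length law — M3.  ``mu_d`` may be real-valued.
    """
    if not (0 < epsilon):
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    if epsilon >= 1:
        return 0
    if r >= 1:
        raise ValueError(f"no convergence horizon: r={r} >= 1")
    rate = (1.0 - r) * p_del * mu_d
    if rate <= 0:
        raise ValueError("need p_del > 0 and mu_d > 0 for a finite horizon")
    if rate >= 1:
        return 1
    return int(math.ceil(math.log(epsilon) / math.log1p(-rate)))


def m1_stationary_pmf(r: float, n_max: int) -> np.ndarray:
    """Exact stationary law of M1 on ``{0..n_max}``.

    Detailed balance of the birth-death chain (birth ``p_ins (L+1)``, death
    ``p_del L``) gives the geometric law ``pi(n) = (1 - r) r^n``; the
    returned vector is truncated at ``n_max`` and renormalized.
    """
    if not (0 <= r < 1):
        raise ValueError(f"r must lie in [0, 1), got {r}")
    n = np.arange(n_max + 1, dtype=float)
    if r == 0:
        p = np.zeros(n_max + 1)
        p[0] = 1.0
        return p
    p = (1.0 - r) * r ** n
    return p / p.sum()


def chain_stationary_pmf(params, L_max: int) -> np.ndarray:
    """Exact stationary vector of the one-generation length chain on ``0..L_max``.

    From state ``L``, an insertion of length ``i`` occurs with probability
    ``p_ins f(i) (L+1)`` (transitions past ``L_max`` are reflected into
    ``L_max``), and a deletion of length ``d`` with the border-thinned
    probability ``p_del g(d) max(L-d+1, 0)``; the residual mass is a
    self-loop.  Event probabilities are jointly rescaled so the matrix is
    stochastic — an exact operation, since rescaling both rates leaves the
    stationary law unchanged.  The balance equations are solved directly
    (sparse LU with one row replaced by the normalization constraint).

    The caller is responsible for choosing ``L_max`` large enough that the
    stationary mass near the boundary is negligible.
    """
    ins_pmf = params.ins_dist.pmf()
    del_pmf = params.del_dist.pmf()
    p_ins, p_del = params.p_ins, params.p_del
    n_states = L_max + 1
    L = np.arange(n_states, dtype=float)

    # joint rescale: stationary law is invariant, matrix becomes stochastic
    max_mass = p_ins * (L_max + 1) + p_del * L_max
    if max_mass > 0.5:
        c = 0.5 / max_mass
        p_ins, p_del = p_ins * c, p_del * c

    rows, cols, data = [], [], []
    states = np.arange(n_states)
    for i, fi in enumerate(ins_pmf, start=1):
        if fi == 0.0:
            continue
        rows.append(states)
        cols.append(np.minimum(states + i, L_max))
        data.append(p_ins * fi * (L + 1.0))
    for d, gd in enumerate(del_pmf, start=1):
        if gd == 0.0:
            continue
        w = p_del * gd * np.maximum(L - d + 1.0, 0.0)
        mask = w > 0.0
        rows.append(states[mask])
        cols.append(states[mask] - d)
        data.append(w[mask])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)

    off = sp.coo_matrix((data, (rows, cols)), shape=(n_states, n_states)).tocsr()
    row_sums = np.asarray(off.sum(axis=1)).ravel()
    if np.any(row_sums > 1.0 + 1e-12):
        raise ValueError("event probabilities exceed 1 after rescaling")
    diag = sp.diags(1.0 - row_sums)
    P = off + diag

    # stationary vector: (P^T - I) x = 0, sum(x) = 1
    A = (P.T - sp.identity(n_states, format="csr")).tolil()
    A[n_states - 1, :] = 1.0
    b = np.zeros(n_states)
    b[-1] = 1.0
    x = spsolve(A.tocsc(), b)
    x = np.clip(x, 0.0, None)
    return x / x.sum()


def m1_trajectory(n_generations: int, L0: float, p_ins: float,
                  p_del: float) -> ExpectationTrajectory:
    """Expectation trajectory of M1 over ``0..n_generations`` generations."""
    values = m1_expectation(np.arange(n_generations + 1), L0, p_ins, p_del)
    if p_ins < p_del:
        L_inf = p_ins / (p_del - p_ins)
    else:
        L_inf = math.inf
    return ExpectationTrajectory(values=np.atleast_1d(values), L0=float(L0),
                                 L_inf=L_inf)


def m2_trajectory(n_generations: int, L0: float, r: float, p_del: float,
                  mu_d: float) -> ExpectationTrajectory:
    """Expectation trajectory of M2 over ``0..n_generations`` generations."""
    values = m2_expectation(np.arange(n_generations + 1), L0, r, p_del, mu_d)
    return ExpectationTrajectory(values=np.atleast_1d(values), L0=float(L0),
                                 L_inf=m2_stationary_mean(r, mu_d))
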