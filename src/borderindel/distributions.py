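"""Indel-length laws.

An insertion or deletion event carries a length drawn from a small discrete
distribution on ``{1, ..., m_max}``.  Two laws are supported:

* ``constant`` — every event has the same length (the fixed-size model M2);
* ``zipf`` — a truncated Zipfian (power-law) pmf ``k^-a / sum_i i^-a`` on
  ``{1..m_max}``, the standard empirical law for indel lengths (model M3).

The Zipf exponent ``a`` is rarely reported directly; what is reported is the
mean indel length (e.g. 16.5 bp for insertions, 4.5 bp for deletions in
mammalian introns).  :func:`zipf_exponent_for_mean` inverts the mean to an
exponent, which is well defined because the mean is strictly decreasing in
``a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

#: Default truncation of the Zipfian indel-length law, in bp.
DEFAULT_M_MAX = 150

#: Upper bracket for the Zipf exponent when inverting a target mean.
_A_MAX = 50.0


def zipf_pmf(k, a: float, m_max: int = DEFAULT_M_MAX):
    """Truncated Zipfian probability ``k^-a / sum_{i=1}^{m_max} i^-a``.

    Parameters
    ----------
    k : int or array of int
        Length(s) in ``{1..m_max}``.
    a : float
        Nonnegative exponent; ``a = 0`` is the uniform law.
    m_max : int
        Truncation (maximum indel length).
    """
    if a < 0:
        raise ValueError(f"Zipf exponent must be nonnegative, got {a}")
    if m_max < 1:
        raise ValueError(f"m_max must be a positive integer, got {m_max}")
    k_arr = np.asarray(k)
    if np.any((k_arr < 1) | (k_arr > m_max)):
        raise ValueError(f"length k={k} outside support 1..{m_max}")
    support = np.arange(1, m_max + 1, dtype=float)
    norm = (support ** (-float(a))).sum()
    out = k_arr.astype(float) ** (-float(a)) / norm
    return float(out) if np.isscalar(k) else out


def zipf_mean(a: float, m_max: int = DEFAULT_M_MAX) -> float:
    """Mean of the truncated Zipfian law with exponent ``a`` on ``{1..m_max}``."""
    support = np.arange(1, m_max + 1, dtype=float)
    w = support ** (-float(a))
    return float((support * w).sum() / w.sum())


def zipf_exponent_for_mean(target_mean: float, m_max: int = DEFAULT_M_MAX) -> float:
    """Exponent ``a >= 0`` whose truncated Zipfian mean equals ``target_mean``.

    The mean decreases strictly from ``(m_max+1)/2`` at ``a=0`` towards 1 as
    ``a`` grows, so the root is unique; it is bracketed on ``[0, 50]`` and
    found by Brent's method.
    """
    if m_max < 1:
        raise ValueError(f"m_max must be a positive integer, got {m_max}")
    uniform_mean = (m_max + 1) / 2.0
    if not (1.0 < target_mean <= uniform_mean):
        raise ValueError(
            f"target mean {target_mean} not achievable on 1..{m_max} "
            f"(must lie in (1, {uniform_mean}])"
        )
    if target_mean == uniform_mean:
        return 0.0
    lo_val = zipf_mean(0.0, m_max) - target_mean
    hi_val = zipf_mean(_A_MAX, m_max) - target_mean
    if hi_val > 0:  # target below what a=50 can reach (mean ~1)
        raise ValueError(f"target mean {target_mean} too close to 1 for bracket")
    a = brentq(lambda x: zipf_mean(x, m_max) - target_mean, 0.0, _A_MAX,
               xtol=1e-10, rtol=1e-12)
    return float(a)


@dataclass
class IndelLengthDistribution:
    """Length law of a single indel event on the support ``{1..max_length}``.

    Use the :meth:`constant` or :meth:`zipf` constructors rather than the
    raw initializer.
    """

    kind: str
    length: Optional[int] = None
    a: Optional[float] = None
    m_max: Optional[int] = None
    _pmf: np.ndarray = field(default=None, repr=False, compare=False)

    @classmethod
    def constant(cls, length: int) -> "IndelLengthDistribution":
        """All events have exactly ``length`` bp."""
        length = int(length)
        if length < 1:
            raise ValueError(f"constant indel length must be >= 1, got {length}")
        return cls(kind="constant", length=length)

    @classmethod
    def zipf(cls, a: Optional[float] = None, m_max: int = DEFAULT_M_MAX,
             mean: Optional[float] = None) -> "IndelLengthDistribution":
        """Truncated Zipfian law, specified by exponent ``a`` or by ``mean``.

        Exactly one of ``a`` and ``mean`` must be given; a ``mean`` is
        inverted to an exponent with :func:`zipf_exponent_for_mean`.
        """
        if (a is None) == (mean is None):
            raise ValueError("specify exactly one of 'a' and 'mean'")
        if mean is not None:
            a = zipf_exponent_for_mean(mean, m_max)
        if a < 0:
            raise ValueError(f"Zipf exponent must be nonnegative, got {a}")
        return cls(kind="zipf", a=float(a), m_max=int(m_max))

    @classmethod
    def from_config(cls, spec: dict) -> "IndelLengthDistribution":
        """Build from a config mapping.

        ``{"kind": "constant", "length": 5}`` or
        ``{"kind": "zipf", "a": 1.5, "m_max": 150}`` or
        ``{"kind": "zipf", "mean": 4.5, "m_max": 150}``.
        """
        kind = spec.get("kind")
        if kind == "constant":
            return cls.constant(spec["length"])
        if kind == "zipf":
            return cls.zipf(a=spec.get("a"), m_max=spec.get("m_max", DEFAULT_M_MAX),
                            mean=spec.get("mean"))
        raise ValueError(f"unknown distribution kind {kind!r}")

    @property
    def max_length(self) -> int:
        return self.length if self.kind == "constant" else self.m_max

    def pmf(self) -> np.ndarray:
        """Probability vector over lengths ``1..max_length`` (sums to 1)."""
        if self._pmf is None:
            if self.kind == "constant":
                p = np.zeros(self.length)
                p[-1] = 1.0
            else:
                support = np.arange(1, self.m_max + 1, dtype=float)
                w = support ** (-self.a)
                p = w / w.sum()
            self._pmf = p
        return self._pmf

    def cdf(self) -> np.ndarray:
        c = np.cumsum(self.pmf())
        c[-1] = 1.0
        return c

    def mean(self) -> float:
        if self.kind == "constant":
            return float(self.length)
        return zipf_mean(self.a, self.m_max)

    def sample(self, rng: np.random.Generator, size=None):
        """Draw length(s) by inverse-CDF lookup (exact for this small support)."""
        if self.kind == "constant":
            if size is None:
                return self.length
            return np.full(size, self.length, dtype=np.int64)
        u = rng.random(size)
        idx = np.searchsorted(self.cdf(), u, side="right")
        out = idx + 1
        return int(out) if size is None else out.astype(np.int64)


def dist_mean(dist: IndelLengthDistribution) -> float:
    """Expected indel length of ``dist`` (the μ of a length law)."""
    return dist.mean()


def sample_length(dist: IndelLengthDistribution, rng: np.random.Generator, size=None):
    """Draw indel length(s) from ``dist`` using ``rng``."""
    return dist.sample(rng, size=size)
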