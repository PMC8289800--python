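"""Closed-form maximal Lyapunov exponents.

The maximal Lyapunov exponent

    phi = lim (1/n) log || M(E_1) ... M(E_n) ||   in [-inf, inf)

of the stationary product of mean matrices along the environment chain
measures the fitness of a strategy: phi > 0 means the population
survives with positive probability, phi < 0 means certain extinction.

Exact values are available in the rank-1 cases:

* scalar (1-type) processes — a stationary average of log-means;
* strategy pairs whose two mean matrices both have rank one — a
  trace formula obtained from the inner products of their rank-1
  factors, specialized below to the responsive, preliminary and
  zero-determinant stochastic switchers.

All exponents are on the natural-log scale.  ``log 0 = -inf`` is
propagated rather than raised: a strategy that is extinction-certain in
some reachable configuration simply has exponent ``-inf``.

The (unlogged) Perron root is kept separate: for a constant environment
it is the per-generation growth *factor* of the expected population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .environment import EnvironmentParams
from .strategies import StrategyPair, rank_class, validate_mean_matrix

__all__ = [
    "LyapunovResult",
    "perron_root",
    "lyapunov_scalar",
    "lyapunov_rank1",
    "lyapunov_responsive",
    "lyapunov_preliminary",
    "lyapunov_stochastic_rank1",
]

_METHODS = frozenset({
    "exact-rank1", "exact-scalar", "perron", "mc",
    "bound-lower", "bound-upper", "sandwich",
})


@dataclass(frozen=True)
class LyapunovResult:
    """An exponent value with its provenance.

    ``value`` lives in [-inf, inf); ``method`` tags how it was obtained;
    ``stderr`` is present only for Monte-Carlo estimates.
    """

    value: float
    method: str
    stderr: float | None = None

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")
        if self.value == math.inf:
            raise ValueError("exponent must be < +inf")


def _log(x: float) -> float:
    """Natural log with log(0) = -inf (no exception)."""
    return math.log(x) if x > 0.0 else -math.inf


def perron_root(M: np.ndarray) -> float:
    """Spectral radius of a nonnegative matrix.

    For an irreducible nonnegative matrix this is the simple Perron
    eigenvalue; in a constant environment it is the growth factor of the
    expected population per generation (not log-scaled).
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError("perron_root requires a nonnegative matrix")
    return float(np.max(np.abs(np.linalg.eigvals(M))))


def lyapunov_scalar(
    m1: float, m2: float, env: EnvironmentParams
) -> LyapunovResult:
    """Exponent of a 1-type process with per-environment means m1, m2.

    The product of scalars obeys the ergodic theorem directly:

        phi = (s2 * log m1 + s1 * log m2) / (s1 + s2)
            = E_pi[log m(I_0)].
    """
    if m1 < 0 or m2 < 0:
        raise ValueError("offspring means must be >= 0")
    value = (env.s2 * _log(m1) + env.s1 * _log(m2)) / (env.s1 + env.s2)
    return LyapunovResult(value, "exact-scalar")


def lyapunov_rank1(pair: StrategyPair, env: EnvironmentParams) -> LyapunovResult:
    """Exact exponent for a pair of rank-1 mean matrices.

    With M(e) = l(e) r(e)^T, the product telescopes through the inner
    products <r(I_k), l(I_{k+1})> and the ergodic theorem gives

        phi = [ s2 log tr M(1) + s1 log tr M(2)
                + s1 s2 log( tr(M(1)M(2)) / (tr M(1) tr M(2)) ) ] / (s1+s2).

    Preconditions: both matrices rank 1 with positive trace, and
    tr(M(1)M(2)) > 0.
    """
    M1, M2 = pair.M1, pair.M2
    for e, M in ((1, M1), (2, M2)):
        if rank_class(M) != 1:
            raise ValueError(
                f"M({e}) has rank 2; no closed form exists - use the "
                "lyapunov_bounds module or the Monte-Carlo estimator"
            )
    t1 = float(np.trace(M1))
    t2 = float(np.trace(M2))
    t12 = float(np.trace(M1 @ M2))
    if t1 <= 0 or t2 <= 0:
        raise ValueError("rank-1 formula requires tr M(e) > 0 for both e")
    if t12 <= 0:
        raise ValueError("rank-1 formula requires tr(M(1)M(2)) > 0")
    s1, s2 = env.s1, env.s2
    value = (
        s2 * math.log(t1) + s1 * math.log(t2)
        + s1 * s2 * math.log(t12 / (t1 * t2))
    ) / (s1 + s2)
    return LyapunovResult(value, "exact-rank1")


def lyapunov_responsive(
    m1: float, m2: float, d1: float, d2: float, env: EnvironmentParams
) -> LyapunovResult:
    """Closed-form exponent of the responsive switcher.

        phi = [ s2 log m1 + s1 log(1-d2)
                + s1 s2 log( m2(1-d1) / (m1(1-d2)) ) ] / (s1+s2).
    """
    if not (m1 > 0 and m2 > 0):
        raise ValueError("offspring means m1, m2 must be > 0")
    if not (0.0 <= d1 < 1.0 and 0.0 <= d2 < 1.0):
        raise ValueError("death probabilities d1, d2 must lie in [0, 1)")
    s1, s2 = env.s1, env.s2
    value = (
        s2 * math.log(m1) + s1 * math.log(1.0 - d2)
        + s1 * s2 * math.log(m2 * (1.0 - d1) / (m1 * (1.0 - d2)))
    ) / (s1 + s2)
    return LyapunovResult(value, "exact-rank1")


def lyapunov_preliminary(
    m1: float, m2: float, d1: float, d2: float, env: EnvironmentParams
) -> LyapunovResult:
    """Closed-form exponent of the preliminary (anticipatory) switcher.

        phi = [ s2 log(1-d1) + s1 log m2
                + s1 s2 log( m1(1-d2) / (m2(1-d1)) ) ] / (s1+s2).
    """
    if not (m1 > 0 and m2 > 0):
        raise ValueError("offspring means m1, m2 must be > 0")
    if not (0.0 <= d1 < 1.0 and 0.0 <= d2 < 1.0):
        raise ValueError("death probabilities d1, d2 must lie in [0, 1)")
    s1, s2 = env.s1, env.s2
    value = (
        s2 * math.log(1.0 - d1) + s1 * math.log(m2)
        + s1 * s2 * math.log(m1 * (1.0 - d2) / (m2 * (1.0 - d1)))
    ) / (s1 + s2)
    return LyapunovResult(value, "exact-rank1")


def lyapunov_stochastic_rank1(
    m_a: float,
    m_d: float,
    alpha: float,
    w1: float,
    w2: float,
    env: EnvironmentParams,
    det_tol: float = 1e-9,
) -> LyapunovResult:
    """Closed-form exponent of the zero-determinant stochastic switcher.

    Requires det M(1) = det M(2) = 0, i.e. the dormant row is the
    scaled copy ``1 - w_e - d_e = w_e * m_d / m_a``.  Then

        phi = [ s2 log(m_a + w1 m_d/m_a)
                + s1 log(alpha m_a + w2 m_d/m_a) ] / (s1+s2).
    """
    if not (m_a > 0 and m_d > 0):
        raise ValueError("offspring means m_a, m_d must be > 0")
    # dormant persistence implied by det = 0
    for name, w in (("w1", w1), ("w2", w2)):
        stay = w * m_d / m_a
        if not (0.0 <= w <= 1.0) or w + stay > 1.0 + det_tol:
            raise ValueError(
                f"{name}={w} with m_d/m_a={m_d / m_a} does not define a "
                "sub-stochastic dormant row under det M = 0"
            )
    s1, s2 = env.s1, env.s2
    value = (
        s2 * _log(m_a + w1 * m_d / m_a)
        + s1 * _log(alpha * m_a + w2 * m_d / m_a)
    ) / (s1 + s2)
    return LyapunovResult(value, "exact-rank1")
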