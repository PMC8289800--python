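"""Fitness maps over the environment plane (s1, s2).

For a family of strategies, each grid point of environmental switching
probabilities is classified by the strategies' Lyapunov exponents: the
winner is the argmax, a strategy is supercritical when its exponent is
positive, and the winner holds a *strong* advantage when it alone is
supercritical — survival is possible for it and certain extinction for
every competitor.

Exponent dispatch: sleepless pairs use the scalar rule, rank-1 pairs
(responsive, preliminary, zero-determinant stochastic, fair-comparison
mixtures) the exact trace formula; genuine rank-2 pairs fall back to
Monte-Carlo (or a bound pair) since no closed form exists.

The responsive-versus-stochastic separatrix under gamma-weighted fair
comparison is also provided in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import EnvironmentParams
from .strategies import StrategyPair, rank_class
from .lyapunov_exact import (
    LyapunovResult,
    lyapunov_rank1,
    lyapunov_scalar,
)
from .lyapunov_mc import mc_lyapunov
from .lyapunov_bounds import build_a_map, upper_bound_spectral, norm_bounds

__all__ = [
    "ClassifiedPoint",
    "compute_exponent",
    "classify_point",
    "sweep",
    "separatrix_res_vs_sto",
]


@dataclass(frozen=True)
class ClassifiedPoint:
    """Classification of a strategy family at one environment point.

    ``advantage_class`` is ``strong`` (winner supercritical, everyone
    else subcritical), ``advantage-supercritical`` (winner positive but
    not alone), or ``subcritical-all``.  Ties within the tolerance are
    reported as winner ``"tie"``.
    """

    s1: float
    s2: float
    exponents: dict
    winner: str
    n_supercritical: int
    strong_advantage: bool
    advantage_class: str


def compute_exponent(
    pair: StrategyPair,
    env: EnvironmentParams,
    method: str = "auto",
    n_steps: int = 20_000,
    n_reps: int = 8,
    seed: int | None = 0,
) -> LyapunovResult:
    """Exponent of a strategy with automatic method dispatch.

    ``auto``: scalar rule for sleepless pairs, exact rank-1 formula
    when both matrices are rank 1, Monte-Carlo otherwise.  ``mc``
    forces Monte-Carlo; ``exact`` raises on rank-2 input; ``bounds``
    returns the midpoint of the best simple bracket (spectral upper,
    one-step lower) tagged as a bound.
    """
    if pair.reducible or pair.kind == "sleepless":
        return lyapunov_scalar(float(pair.M1[0, 0]), float(pair.M2[0, 0]), env)
    is_rank1 = rank_class(pair.M1) == 1 and rank_class(pair.M2) == 1
    if method == "auto":
        method = "exact" if is_rank1 else "mc"
    if method == "exact":
        return lyapunov_rank1(pair, env)
    if method == "mc":
        return mc_lyapunov(pair, env, n_steps=n_steps, n_reps=n_reps, seed=seed)
    if method == "bounds":
        up = upper_bound_spectral(build_a_map(pair), env, lam="one")
        lo, _ = norm_bounds(pair, env)
        mid = 0.5 * (up.value + lo.value)
        return LyapunovResult(mid if math.isfinite(mid) else -math.inf, "sandwich")
    raise ValueError(f"unknown method {method!r}")


def classify_point(
    strategies: list[StrategyPair],
    env: EnvironmentParams,
    method: str = "auto",
    tie_tol: float = 1e-9,
    n_steps: int = 20_000,
    n_reps: int = 8,
    seed: int | None = 0,
) -> ClassifiedPoint:
    """Classify a family of strategies at one (s1, s2) point."""
    if not strategies:
        raise ValueError("need at least one strategy")
    expo = {
        p.label: compute_exponent(p, env, method, n_steps, n_reps, seed).value
        for p in strategies
    }
    best = max(expo.values())
    winners = [lab for lab, v in expo.items() if v >= best - tie_tol]
    winner = winners[0] if len(winners) == 1 else "tie"
    n_super = sum(1 for v in expo.values() if v > 0.0)
    strong = len(winners) == 1 and best > 0.0 and n_super == 1
    if strong:
        cls = "strong"
    elif best > 0.0:
        cls = "advantage-supercritical"
    else:
        cls = "subcritical-all"
    return ClassifiedPoint(env.s1, env.s2, expo, winner, n_super, strong, cls)


def sweep(
    strategies: list[StrategyPair],
    s1_grid: np.ndarray,
    s2_grid: np.ndarray,
    method: str = "auto",
    tie_tol: float = 1e-9,
    n_steps: int = 20_000,
    n_reps: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Classify every node of an (s1, s2) grid.

    Returns a tidy frame with one row per node: s1, s2, one
    ``phi_<label>`` column per strategy, winner, n_supercritical and
    advantage_class.  The corner s1 = s2 = 1 is clipped to 1 - 1e-9 to
    stay inside the ergodic region.  Monte-Carlo nodes draw their seed
    deterministically from the grid coordinates so the sweep is
    reproducible point by point.
    """
    rows = []
    for i1, s1 in enumerate(np.asarray(s1_grid, dtype=float)):
        for i2, s2 in enumerate(np.asarray(s2_grid, dtype=float)):
            if s1 * s2 >= 1.0:
                s1c = min(s1, 1.0 - 1e-9)
                s2c = min(s2, 1.0 - 1e-9)
            else:
                s1c, s2c = s1, s2
            env = EnvironmentParams(s1c, s2c)
            node_seed = (seed * 1_000_003 + i1 * 1009 + i2) % (2**31)
            cp = classify_point(
                strategies, env, method, tie_tol, n_steps, n_reps, node_seed
            )
            row = {"s1": s1c, "s2": s2c}
            row.update({f"phi_{k}": v for k, v in cp.exponents.items()})
            row.update(
                winner=cp.winner,
                n_supercritical=cp.n_supercritical,
                advantage_class=cp.advantage_class,
            )
            rows.append(row)
    return pd.DataFrame(rows)


def separatrix_res_vs_sto(
    s1: float,
    alpha: float,
    gamma: float = 1.0,
    m_a: float | None = None,
    m_d: float | None = None,
    w1: float = 0.4,
    w2: float = 0.4,
) -> float:
    """Responsive-vs-stochastic separatrix under gamma-weighted fair
    comparison: the s2 at which the two exponents coincide,

        s2 = s1 ( log(w2 + w2 m_d/m_a) - log(alpha m_a + w2 m_d/m_a) )
             / ( log(m_a + w1 m_d/m_a) - log(m_a + gamma m_d)
                 - s1 log(alpha w1 / (gamma w2)) ).

    ``m_a``/``m_d`` default to the budget-matched 4/(1+gamma).  A
    vanishing denominator (pole) returns NaN.
    """
    if m_a is None:
        m_a = 4.0 / (1.0 + gamma)
    if m_d is None:
        m_d = 4.0 / (1.0 + gamma)
    if min(s1, alpha, gamma, m_a, m_d, w1, w2) <= 0:
        raise ValueError("all separatrix arguments must be positive")
    num = s1 * (
        math.log(w2 + w2 * m_d / m_a) - math.log(alpha * m_a + w2 * m_d / m_a)
    )
    den = (
        math.log(m_a + w1 * m_d / m_a)
        - math.log(m_a + gamma * m_d)
        - s1 * math.log(alpha * w1 / (gamma * w2))
    )
    if den == 0.0:
        return math.nan
    return num / den
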