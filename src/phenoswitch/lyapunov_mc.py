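"""Stochastic and enumeration-based Lyapunov-exponent estimators.

Two complementary numerical routes to the maximal Lyapunov exponent:

* :func:`mc_lyapunov` — simulate environment paths and accumulate
  ``(1/n) log || M(e_1) ... M(e_n) ||`` with per-step renormalization
  (the running product is divided by its entry sum each step, the log
  scale carried in an accumulator, so products of length 1e5 neither
  overflow nor underflow).  Replicates are independent; the mean and
  standard error across replicates are reported.

* :func:`sandwich_bounds` — the monotone sandwich: for a
  super-multiplicative functional ``f`` and a sub-multiplicative norm,

      phi_lower_k = (1/k) E[ log f(M_1 ... M_k) ]   increases to phi,
      phi_upper_k = (1/k) E[ log ||M_1 ... M_k|| ]  decreases to phi,

  with the expectations computed *exactly* by enumerating all 2^k
  environment paths of length k under the stationary chain weights.
"""

from __future__ import annotations

import math

import numpy as np

from .environment import EnvironmentParams, _simulate_paths, transition_matrix, stationary_distribution
from .strategies import StrategyPair
from .lyapunov_exact import LyapunovResult

__all__ = ["mc_lyapunov", "sandwich_bounds", "SUPER_MULTIPLICATIVE"]


def _per(M: np.ndarray) -> float:
    """Permanent of a 2x2 matrix: per(M) = ad + bc."""
    return float(M[0, 0] * M[1, 1] + M[0, 1] * M[1, 0])


#: super-multiplicative functionals for the sandwich lower bound
SUPER_MULTIPLICATIVE = {
    "permanent": _per,
    "min-row-sum": lambda M: float(M.sum(axis=1).min()),
    "min-col-sum": lambda M: float(M.sum(axis=0).min()),
    "diag1": lambda M: float(M[0, 0]),
    "diag2": lambda M: float(M[1, 1]),
}

_NORMS = {
    "sum": lambda M: float(np.abs(M).sum()),
    "l1": lambda M: float(np.abs(M).sum(axis=0).max()),
    "linf": lambda M: float(np.abs(M).sum(axis=1).max()),
}


def mc_lyapunov(
    pair: StrategyPair,
    env: EnvironmentParams,
    n_steps: int = 100_000,
    n_reps: int = 16,
    seed: int | np.random.Generator | None = None,
) -> LyapunovResult:
    """Monte-Carlo estimate of the maximal Lyapunov exponent.

    Simulates ``n_reps`` independent stationary environment paths of
    length ``n_steps``, multiplies the mean matrices along each path
    with per-step renormalization, and returns the replicate mean with
    its standard error.  All replicates are advanced in lock-step with
    vectorized 2x2 arithmetic.
    """
    if n_steps < 100:
        raise ValueError(f"n_steps must be >= 100, got {n_steps}")
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    rng = np.random.default_rng(seed)

    a1, b1, c1, d1 = (float(x) for x in pair.M1.ravel())
    a2, b2, c2, d2 = (float(x) for x in pair.M2.ravel())

    # running 2x2 products, one per replicate
    p11 = np.ones(n_reps)
    p12 = np.zeros(n_reps)
    p21 = np.zeros(n_reps)
    p22 = np.ones(n_reps)
    acc = np.zeros(n_reps)
    dead = np.zeros(n_reps, dtype=bool)

    pi1 = env.s2 / (env.s1 + env.s2)
    states = np.where(rng.random(n_reps) < pi1, 1, 2).astype(np.int8)

    for _ in range(n_steps):
        in1 = states == 1
        a = np.where(in1, a1, a2)
        b = np.where(in1, b1, b2)
        c = np.where(in1, c1, c2)
        d = np.where(in1, d1, d2)
        q11 = p11 * a + p12 * c
        q12 = p11 * b + p12 * d
        q21 = p21 * a + p22 * c
        q22 = p21 * b + p22 * d
        s = q11 + q12 + q21 + q22  # entrywise-sum norm (all entries >= 0)
        alive = s > 0.0
        dead |= ~alive
        safe = np.where(alive, s, 1.0)
        with np.errstate(divide="ignore"):
            acc += np.where(alive, np.log(safe), 0.0)
        p11, p12, p21, p22 = q11 / safe, q12 / safe, q21 / safe, q22 / safe
        u = rng.random(n_reps)
        switch = np.where(in1, u < env.s1, u < env.s2)
        states = np.where(switch, 3 - states, states)

    vals = np.where(dead, -np.inf, acc / n_steps)
    if np.any(dead):
        return LyapunovResult(-math.inf, "mc", stderr=0.0)
    mean = float(vals.mean())
    stderr = float(vals.std(ddof=1) / math.sqrt(n_reps)) if n_reps > 1 else math.inf
    return LyapunovResult(mean, "mc", stderr=stderr)


def sandwich_bounds(
    pair: StrategyPair,
    env: EnvironmentParams,
    k: int,
    f: str = "permanent",
    norm: str = "sum",
) -> tuple[float, float]:
    """Exact k-step sandwich bounds ``(phi_lower_k, phi_upper_k)``.

    Enumerates every environment path of length ``k`` (initial state
    stationary, transitions by the chain), sharing prefix products so
    the work is O(2^k) matrix multiplications.  The lower sequence is
    nondecreasing in k, the upper nonincreasing, and both converge to
    the true exponent.  ``k`` is limited to 16.
    """
    if not (1 <= k <= 16):
        raise ValueError(f"k must lie in 1..16, got {k}")
    try:
        flo = SUPER_MULTIPLICATIVE[f]
    except KeyError:
        raise ValueError(
            f"unknown functional {f!r}; choose from {sorted(SUPER_MULTIPLICATIVE)}"
        ) from None
    try:
        fup = _NORMS[norm]
    except KeyError:
        raise ValueError(f"unknown norm {norm!r}; choose from {sorted(_NORMS)}") from None

    P = transition_matrix(env)
    pi = stationary_distribution(env)
    mats = {1: pair.M1, 2: pair.M2}

    lower = 0.0
    upper = 0.0
    # depth-first over the path tree, sharing prefix products
    stack = [(1, e, pi[e - 1], mats[e], 0.0) for e in (1, 2)]
    while stack:
        depth, state, prob, prod, scale = stack.pop()
        if prob == 0.0:
            continue
        if depth == k:
            v = flo(prod)
            lower += prob * (scale + math.log(v) if v > 0 else -math.inf)
            upper += prob * (scale + math.log(fup(prod)))
            continue
        for nxt in (1, 2):
            p = prob * P[state - 1, nxt - 1]
            if p == 0.0:
                continue
            new = prod @ mats[nxt]
            s = float(np.abs(new).sum())
            if s > 0:
                stack.append((depth + 1, nxt, p, new / s, scale + math.log(s)))
            else:
                lower += p * -math.inf
                upper += p * -math.inf
    return lower / k, upper / k
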