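"""Individual-level branching simulator and constant-environment analytics.

The population model is a two-type Bienaymé–Galton–Watson process whose
second (dormant) type is constrained to wake, stay dormant, or die —
its offspring support is ``{(0,0), (1,0), (0,1)}``.  Offspring laws are
finite distributions on pairs (n_active, n_dormant), possibly differing
between the two environment states.

The concrete *binary dormancy model* is a caricature of bacterial
reproduction by fission and sporulation: an active cell dies with
probability ``1-p+eps``, splits in two with probability ``(p-eps)b``
and sporulates (switches to the dormant state) with probability
``(p-eps)(1-b)``; a dormant cell wakes with probability ``w``, dies
with probability ``d``, and persists otherwise.  ``eps`` is the
reproductive trade-off carried by the dormancy trait; the 1-type
benchmark ("sleepless") simply splits with probability ``p`` or dies.

In a constant environment everything of interest follows from the joint
probability generating functions: the minimal fixed point gives the
per-starting-type extinction probabilities, n-fold composition gives
the extinction-by-generation-n curve, and summing the survival tail
gives the expected extinction time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .environment import EnvironmentParams, _simulate_paths, simulate_path

__all__ = [
    "OffspringLaw",
    "constant_law",
    "BinaryDormancyParams",
    "Trajectory",
    "binary_dormancy_law",
    "binary_sleepless_law",
    "law_from_mean_matrix",
    "mean_matrix_of_law",
    "simulate_population",
    "simulate_survival",
    "extinction_probability_constant",
    "closed_form_sigma",
    "survival_tail",
    "check_domination_condition",
    "tail_advantage_condition",
    "expected_extinction_time",
]

_DORMANT_SUPPORT = {(0, 0), (1, 0), (0, 1)}

ACTIVE, DORMANT = 1, 2


@dataclass(frozen=True)
class OffspringLaw:
    """Finite offspring distributions per environment and parent type.

    ``table[e][t]`` is a list of ``((n_active, n_dormant), prob)``
    entries for environment ``e`` in {1,2} and parent type ``t``
    (1 = active, 2 = dormant).  Probabilities must sum to one per
    (e, t); the dormant-parent support is restricted to
    {(0,0), (1,0), (0,1)}.
    """

    table: dict

    def __post_init__(self) -> None:
        for e in (1, 2):
            if e not in self.table:
                raise ValueError(f"offspring law missing environment {e}")
            for t in (ACTIVE, DORMANT):
                entries = self.table[e].get(t)
                if not entries:
                    raise ValueError(f"offspring law missing parent type {t} in environment {e}")
                tot = 0.0
                for (na, nd), p in entries:
                    if na < 0 or nd < 0 or int(na) != na or int(nd) != nd:
                        raise ValueError(f"offspring counts must be nonnegative integers, got {(na, nd)}")
                    if p < 0:
                        raise ValueError(f"offspring probabilities must be >= 0, got {p}")
                    if t == DORMANT and p > 0 and (na, nd) not in _DORMANT_SUPPORT:
                        raise ValueError(
                            "dormant parents can only wake, stay or die: "
                            f"support point {(na, nd)} is not allowed"
                        )
                    tot += p
                if abs(tot - 1.0) > 1e-9:
                    raise ValueError(
                        f"probabilities for (environment {e}, type {t}) sum to {tot}, not 1"
                    )

    @property
    def constant(self) -> bool:
        """True if the law is the same in both environments."""
        return self.table[1] == self.table[2]

    def entries(self, e: int, t: int) -> list:
        return self.table[e][t]

    def pgf(self, s: np.ndarray, e: int = 1) -> np.ndarray:
        """Joint pgf (f_active(s), f_dormant(s)) at s = (s1, s2)."""
        out = np.empty(2)
        for t in (ACTIVE, DORMANT):
            out[t - 1] = sum(
                p * s[0] ** na * s[1] ** nd for (na, nd), p in self.table[e][t]
            )
        return out


def constant_law(active: list, dormant: list) -> dict:
    """Helper: same offspring table in both environments."""
    side = {ACTIVE: list(active), DORMANT: list(dormant)}
    return {1: side, 2: {ACTIVE: list(active), DORMANT: list(dormant)}}


@dataclass(frozen=True)
class BinaryDormancyParams:
    """Parameters of the binary fission/sporulation model.

    p : division-or-switch propensity, in (0, 1)
    epsilon : reproductive trade-off of the dormancy trait, in [0, p)
    b : division share of a reproduction-or-switch event, in (0, 1]
    w : resuscitation probability of a dormant cell, in (0, 1)
    d : death probability of a dormant cell, in (0, 1-w)
    """

    p: float
    epsilon: float = 0.0
    b: float = 1.0
    w: float = 0.5
    d: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must lie in (0,1), got {self.p!r}")
        if not 0.0 <= self.epsilon < self.p:
            raise ValueError(f"epsilon must lie in [0, p), got {self.epsilon!r}")
        if not 0.0 < self.b <= 1.0:
            raise ValueError(f"b must lie in (0,1], got {self.b!r}")
        if not 0.0 < self.w < 1.0:
            raise ValueError(f"w must lie in (0,1), got {self.w!r}")
        if not 0.0 < self.d < 1.0 - self.w:
            raise ValueError(f"d must lie in (0, 1-w), got {self.d!r}")


def binary_dormancy_law(params: BinaryDormancyParams) -> OffspringLaw:
    """Offspring law of the binary dormancy model (both environments equal).

    Active: (0,0) w.p. 1-p+eps, (2,0) w.p. (p-eps)b, (0,1) w.p. (p-eps)(1-b).
    Dormant: (1,0) w.p. w, (0,0) w.p. d, (0,1) w.p. 1-w-d.
    """
    p, eps, b, w, d = params.p, params.epsilon, params.b, params.w, params.d
    active = [((0, 0), 1.0 - p + eps), ((2, 0), (p - eps) * b), ((0, 1), (p - eps) * (1.0 - b))]
    dormant = [((1, 0), w), ((0, 0), d), ((0, 1), 1.0 - w - d)]
    return OffspringLaw(constant_law(active, dormant))


def binary_sleepless_law(p: float) -> OffspringLaw:
    """1-type splitting law p*delta_2 + (1-p)*delta_0, embedded as 2-type.

    The dormant type is unreachable; its nominal law is immediate death.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0,1), got {p!r}")
    active = [((2, 0), p), ((0, 0), 1.0 - p)]
    dormant = [((0, 0), 1.0)]
    return OffspringLaw(constant_law(active, dormant))


def law_from_mean_matrix(M1: np.ndarray, M2: np.ndarray | None = None) -> OffspringLaw:
    """Canonical minimal-support law realizing given mean matrices.

    For each environment, an active parent produces ``(c_a, 0)`` with
    probability ``m_a/c_a``, ``(0, c_d)`` with probability ``m_d/c_d``
    and ``(0, 0)`` otherwise, with the counts ``c`` chosen as the
    smallest integers >= the mean making the probabilities a
    sub-distribution; the dormant row must already be stochastic
    (wake w, stay 1-w-d, die d).  This lets any mean-matrix strategy be
    realized as an individual-based model with matching first moments.
    """
    def _active(row: np.ndarray) -> list:
        m_a, m_d = float(row[0]), float(row[1])
        c_a = max(1, math.ceil(m_a)) if m_a > 0 else 1
        c_d = max(1, math.ceil(m_d)) if m_d > 0 else 1
        while m_a / c_a + m_d / c_d > 1.0:
            if m_a / c_a >= m_d / c_d:
                c_a += 1
            else:
                c_d += 1
        pa, pd = m_a / c_a, m_d / c_d
        out = []
        if pa > 0:
            out.append(((c_a, 0), pa))
        if pd > 0:
            out.append(((0, c_d), pd))
        rest = 1.0 - pa - pd
        if rest > 0:
            out.append(((0, 0), rest))
        return out

    def _dormant(row: np.ndarray) -> list:
        w, stay = float(row[0]), float(row[1])
        if w + stay > 1.0 + 1e-12:
            raise ValueError(f"dormant row {row} is not sub-stochastic")
        die = max(0.0, 1.0 - w - stay)
        out = []
        if w > 0:
            out.append(((1, 0), w))
        if stay > 0:
            out.append(((0, 1), stay))
        if die > 0:
            out.append(((0, 0), die))
        return out

    M1 = np.asarray(M1, dtype=float)
    M2 = M1 if M2 is None else np.asarray(M2, dtype=float)
    table = {
        1: {ACTIVE: _active(M1[0]), DORMANT: _dormant(M1[1])},
        2: {ACTIVE: _active(M2[0]), DORMANT: _dormant(M2[1])},
    }
    return OffspringLaw(table)


def mean_matrix_of_law(law: OffspringLaw, e: int = 1) -> np.ndarray:
    """Mean matrix of the law in environment e: entry (t,j) is the
    expected number of type-j offspring of a type-t parent."""
    M = np.zeros((2, 2))
    for t in (ACTIVE, DORMANT):
        for (na, nd), p in law.entries(e, t):
            M[t - 1, 0] += p * na
            M[t - 1, 1] += p * nd
    return M


@dataclass
class Trajectory:
    """One realized population path.

    ``generations[n]`` is the (active, dormant) count in generation n
    (index 0 = initial state); ``extinction_gen`` is the first n >= 1
    with a zero population, or None if censored at max_gen;
    ``truncated`` flags a supercritical blow-up beyond the cap.
    """

    generations: list
    env_path: np.ndarray
    extinction_gen: int | None
    truncated: bool = False

    @property
    def extinct(self) -> bool:
        return self.extinction_gen is not None


def _step_counts(
    counts: np.ndarray, entries: list, rng: np.random.Generator
) -> np.ndarray:
    """Aggregate offspring of `counts[r]` i.i.d. parents per replicate.

    Vectorized multinomial across replicates; returns (n_reps, 2)
    totals of (active, dormant) offspring.
    """
    probs = np.array([p for _, p in entries])
    vecs = np.array([v for v, _ in entries], dtype=np.int64)  # (k, 2)
    # guard tiny negative rounding and renormalize exactly
    probs = np.clip(probs, 0.0, None)
    probs = probs / probs.sum()
    draws = rng.multinomial(counts, probs)  # (n_reps, k)
    return draws @ vecs


def simulate_population(
    law: OffspringLaw,
    env: EnvironmentParams | None = None,
    z0: tuple = (1, 0),
    max_gen: int = 200,
    seed: int | np.random.Generator | None = None,
    cap: int = 10**9,
) -> Trajectory:
    """Simulate one population trajectory generation by generation.

    Each individual draws an i.i.d. offspring vector from the law for
    the current environment state; (0,0) is absorbing.  With ``env``
    None the environment is held constant in state 1.  Populations
    exceeding ``cap`` individuals stop with the ``truncated`` flag set
    (supercritical blow-up), not an exception.
    """
    if max_gen < 1:
        raise ValueError(f"max_gen must be >= 1, got {max_gen}")
    if tuple(z0) == (0, 0):
        raise ValueError("initial population must be nonzero")
    rng = np.random.default_rng(seed)
    if env is None:
        path = np.ones(max_gen, dtype=np.int8)
    else:
        path = simulate_path(env, max_gen, rng)
    gens = [tuple(int(x) for x in z0)]
    na, nd = gens[0]
    extinction = None
    truncated = False
    for n in range(max_gen):
        e = int(path[n])
        tot = np.zeros(2, dtype=np.int64)
        if na > 0:
            tot += _step_counts(np.array([na]), law.entries(e, ACTIVE), rng)[0]
        if nd > 0:
            tot += _step_counts(np.array([nd]), law.entries(e, DORMANT), rng)[0]
        na, nd = int(tot[0]), int(tot[1])
        gens.append((na, nd))
        if na + nd == 0:
            extinction = n + 1
            break
        if na + nd > cap:
            truncated = True
            break
    return Trajectory(gens, path[: len(gens) - 1], extinction, truncated)


def simulate_survival(
    law: OffspringLaw,
    env: EnvironmentParams | None = None,
    z0: tuple = (1, 0),
    max_gen: int = 200,
    n_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
    cap: int = 10**4,
) -> dict:
    """Vectorized replicate study of survival.

    Runs ``n_reps`` independent populations in lock-step (shared
    generation clock, independent environments per replicate) and
    returns extinction generations (``inf`` where censored alive),
    final counts, and the surviving fraction.  Replicates whose size
    exceeds ``cap`` are frozen and counted as survivors — past the cap
    extinction is no longer a practical possibility at these horizons.
    """
    rng = np.random.default_rng(seed)
    active = np.full(n_reps, int(z0[0]), dtype=np.int64)
    dormant = np.full(n_reps, int(z0[1]), dtype=np.int64)
    T = np.full(n_reps, np.inf)
    frozen = np.zeros(n_reps, dtype=bool)
    if env is not None:
        states = _simulate_paths(env, 1, n_reps, rng)[:, 0]
    else:
        states = np.ones(n_reps, dtype=np.int8)

    for n in range(max_gen):
        alive = np.isinf(T) & ~frozen
        if not alive.any():
            break
        new_a = np.where(frozen, active, 0)
        new_d = np.where(frozen, dormant, 0)
        for e in (1, 2):
            sel = alive & (states == e)
            if not sel.any():
                continue
            tot = _step_counts(active[sel], law.entries(e, ACTIVE), rng)
            tot += _step_counts(dormant[sel], law.entries(e, DORMANT), rng)
            new_a[sel] = tot[:, 0]
            new_d[sel] = tot[:, 1]
        active, dormant = new_a, new_d
        died = alive & (active + dormant == 0)
        T[died] = n + 1
        frozen |= np.isinf(T) & (active + dormant > cap)
        if env is not None:
            u = rng.random(n_reps)
            switch = np.where(states == 1, u < env.s1, u < env.s2)
            states = np.where(switch, 3 - states, states).astype(np.int8)

    surviving = np.isinf(T)
    return {
        "T": T,
        "final_active": active,
        "final_dormant": dormant,
        "truncated": frozen,
        "survival_fraction": float(surviving.mean()),
        "n_reps": n_reps,
        "max_gen": max_gen,
    }


def extinction_probability_constant(
    law: OffspringLaw,
    tol: float = 1e-12,
    max_iter: int = 10**6,
) -> np.ndarray:
    """Per-starting-type extinction probabilities (constant environment).

    The minimal fixed point of the joint pgfs, reached by iterating
    ``s <- f(s)`` from ``s = (0, 0)``; monotone convergence is
    guaranteed, linear but possibly slow near criticality.  Survival
    started from one type-t individual is ``1 - q[t-1]``.
    """
    if not law.constant:
        raise ValueError("extinction analytics require a constant-environment law")
    s = np.zeros(2)
    for _ in range(max_iter):
        nxt = law.pgf(s)
        if np.max(np.abs(nxt - s)) < tol:
            return nxt
        s = nxt
    raise RuntimeError(f"pgf fixed-point iteration did not converge in {max_iter} steps")


def closed_form_sigma(kind: str, params) -> float:
    """Closed-form survival probabilities of the binary models.

    * ``sleepless``: sigma = 2 - 1/p for splitting probability p;
    * ``binary-dormancy`` (eps = 0): started active,
      sigma = 2 - 1/(b p) + ((1-b)/b) * w/(w+d).

    Clamped to [0, 1]; subcritical parameters give 0.
    """
    if kind == "sleepless":
        p = float(params if not isinstance(params, dict) else params["p"])
        val = 2.0 - 1.0 / p
    elif kind == "binary-dormancy":
        if isinstance(params, BinaryDormancyParams):
            p, eps, b, w, d = params.p, params.epsilon, params.b, params.w, params.d
        else:
            p, eps, b, w, d = (params[k] for k in ("p", "epsilon", "b", "w", "d"))
        if eps != 0.0:
            raise ValueError("closed form is available only for epsilon = 0")
        val = 2.0 - 1.0 / (b * p) + (1.0 - b) / b * w / (w + d)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return min(1.0, max(0.0, val))


def survival_tail(
    law: OffspringLaw, n_max: int, start: int = ACTIVE
) -> np.ndarray:
    """Exact survival curve P[T > n], n = 0..n_max, by pgf iteration.

    ``P[T > n] = 1 - f^(n)(0)`` evaluated at the starting type; the
    sequence is nonincreasing and tends to 1 - sigma... i.e. the
    extinction-by-n probabilities increase to the total extinction
    probability.
    """
    if not law.constant:
        raise ValueError("survival_tail requires a constant-environment law")
    out = np.empty(n_max + 1)
    out[0] = 1.0
    s = np.zeros(2)
    for n in range(1, n_max + 1):
        s = law.pgf(s)
        out[n] = 1.0 - s[start - 1]
    return out


def check_domination_condition(law_X: OffspringLaw, law_Z: OffspringLaw) -> bool:
    """Offspring-mass domination of the dormancy model by the benchmark.

    True iff for every k >= 1 the total-offspring mass of Z's active law
    at k (summing over all splits into active/dormant) does not exceed
    the benchmark mass Q_X(k).  Under this condition the benchmark
    stochastically dominates the dormancy model's per-parent output.
    """
    def _total_mass(law: OffspringLaw) -> dict:
        mass: dict[int, float] = {}
        for (na, nd), p in law.entries(1, ACTIVE):
            k = int(na + nd)
            mass[k] = mass.get(k, 0.0) + p
        return mass

    mx = _total_mass(law_X)
    mz = _total_mass(law_Z)
    ks = set(mx) | set(mz)
    return all(mx.get(k, 0.0) + 1e-12 >= mz.get(k, 0.0) for k in ks if k >= 1)


def tail_advantage_condition(
    params: BinaryDormancyParams, mu_X: float
) -> tuple[bool, str]:
    """Explicit criterion for prolonged subcritical survival.

    In the subcritical regime (mu_X < 1) the dormancy model outlives the
    benchmark in the tail sense (P[T_Z > n] > P[T_X > n] eventually)
    whenever

        1 - d > mu_X   and   w < (1 - d - mu_X) *
                (mu_X - E[Z1_active]) / (mu_X - E[Z1_active + Z1_dormant]),

    with the Z-moments taken from the active-parent law.  Returns
    (holds, diagnostic).
    """
    if not mu_X < 1.0:
        return False, f"requires subcritical benchmark, got mu_X={mu_X}"
    law = binary_dormancy_law(params)
    M = mean_matrix_of_law(law)
    ez_a = float(M[0, 0])
    ez_tot = float(M[0, 0] + M[0, 1])
    d, w = params.d, params.w
    if not 1.0 - d > mu_X:
        return False, f"1-d={1 - d} is not > mu_X={mu_X}"
    denom = mu_X - ez_tot
    if denom == 0.0:
        return False, "degenerate ratio: mu_X equals the total active-parent mean"
    bound = (1.0 - d - mu_X) * (mu_X - ez_a) / denom
    if w < bound:
        return True, f"w={w} < {bound}"
    return False, f"w={w} is not < {bound}"


def expected_extinction_time(
    law: OffspringLaw,
    cap: int = 10**5,
    start: int = ACTIVE,
    tol: float = 1e-12,
) -> float:
    """E[T] = sum_n P[T > n], or inf when the tail sum diverges.

    The tail is accumulated by pgf iteration up to ``cap`` generations.
    If it has not vanished by then, a decay check over the last decade
    decides: a tail decaying no faster than c/n (the critical rate,
    non-summable) is declared infinite; geometric decay is summed with
    a geometric-remainder correction.
    """
    if not law.constant:
        raise ValueError("expected_extinction_time requires a constant-environment law")
    s = np.zeros(2)
    total = 1.0  # P[T > 0]
    prev_mark = None
    tail = 1.0
    for n in range(1, cap + 1):
        s = law.pgf(s)
        tail = 1.0 - s[start - 1]
        total += tail
        if tail < tol:
            return total
        if n == cap // 10:
            prev_mark = tail
    # tail still alive at cap: classify the decay over the last decade
    if prev_mark is None or prev_mark == 0.0:
        return total
    ratio = tail / prev_mark  # c/n decay gives ~0.1; geometric gives << 0.1
    if ratio > 0.05:
        return math.inf
    # geometric remainder estimate
    r = ratio ** (1.0 / (cap - cap // 10))
    return total + tail * r / (1.0 - r)
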