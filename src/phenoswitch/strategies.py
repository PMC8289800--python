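"""Switching strategies as pairs of per-environment mean matrices.

A strategy of a two-type (active/dormant) branching population in the
binary random environment is summarized by a pair of nonnegative 2x2
mean matrices ``(M(1), M(2))``, one per environment state.  Rows index
the parent type (row 1 = active, row 2 = dormant), columns the offspring
type (col 1 = active, col 2 = dormant).  The general dormancy form is

    M(e) = [[m_a^e, m_d^e],
            [w^e,   1 - w^e - d^e]],

where ``m_a^e``/``m_d^e`` are the mean numbers of active/dormant
offspring of an active parent, and ``w^e``/``d^e`` are the waking and
death probabilities of a dormant parent (dormant individuals can only
wake, stay dormant, or die).

The classic idealized strategies are provided as constructors:

``responsive``
    senses the environment: only active offspring in good times, only
    dormant offspring in bad times;
``preliminary``
    the anticipatory mirror image (dormant offspring in good times,
    active in bad times);
``stochastic``
    environment-independent bet-hedging allocation, harsh-time fecundity
    scaled by ``alpha``;
``sleepless``
    the 1-type benchmark without a dormancy trait, embedded as a
    reducible 2x2 pair.

Two strategies are under *fair comparison* when, in each environment and
for each parent type, they spend the same expected offspring budget; the
gamma-weighted variant prices a dormant offspring at ``gamma`` active
offspring units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MeanMatrix",
    "StrategyPair",
    "CostWeight",
    "validate_mean_matrix",
    "make_responsive",
    "make_preliminary",
    "make_stochastic",
    "make_sleepless",
    "make_convex_combination",
    "make_general",
    "check_fair_comparison",
    "rank_class",
]

#: a mean matrix is simply a nonnegative 2x2 numpy array
MeanMatrix = np.ndarray

#: default scale-aware singularity tolerance for :func:`rank_class`
RANK_TOL = 1e-12

#: default absolute tolerance on row budgets in :func:`check_fair_comparison`
FAIR_TOL = 1e-9


def validate_mean_matrix(M: np.ndarray, *, dormancy: bool = False) -> np.ndarray:
    """Validate (and return) a 2x2 nonnegative mean matrix.

    With ``dormancy=True`` additionally requires the dormant row to be
    sub-stochastic (``m21 + m22 <= 1``): dormant individuals wake, stay,
    or die, nothing else.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (2, 2):
        raise ValueError(f"mean matrix must be 2x2, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise ValueError("mean matrix entries must be finite")
    if np.any(M < 0):
        raise ValueError(f"mean matrix entries must be nonnegative, got\n{M}")
    if dormancy and M[1, 0] + M[1, 1] > 1.0 + 1e-12:
        raise ValueError(
            "dormant row must satisfy m21 + m22 <= 1 "
            f"(wake/stay/die), got row {M[1]}"
        )
    return M


@dataclass(frozen=True)
class CostWeight:
    """Relative resource cost of a dormant offspring (active costs 1)."""

    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma!r}")


@dataclass(frozen=True)
class StrategyPair:
    """A labelled pair of mean matrices, one per environment state.

    Attributes
    ----------
    M1, M2 : numpy.ndarray
        Mean matrices for the healthy (1) and harsh (2) environment.
    label : str
        Display name of the strategy.
    kind : str
        One of ``responsive | preliminary | stochastic | sleepless |
        convex | general``; drives exponent-method dispatch.
    params : dict
        The constructor parameters (empty for ``make_general``).
    reducible : bool
        True for the sleepless embedding, whose second column is zero;
        such pairs are routed to the scalar exponent rule and never to
        Perron-Frobenius-dependent code.
    """

    M1: np.ndarray
    M2: np.ndarray
    label: str
    kind: str = "general"
    params: dict = field(default_factory=dict)
    reducible: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "M1", validate_mean_matrix(self.M1))
        object.__setattr__(self, "M2", validate_mean_matrix(self.M2))

    def matrix(self, e: int) -> np.ndarray:
        """Mean matrix for environment state ``e`` in {1, 2}."""
        if e == 1:
            return self.M1
        if e == 2:
            return self.M2
        raise ValueError(f"environment state must be 1 or 2, got {e}")


def _check_prob(name: str, v: float, *, closed_top: bool = False) -> None:
    hi_ok = v <= 1.0 if closed_top else v < 1.0
    if not (0.0 <= v and hi_ok):
        top = "]" if closed_top else ")"
        raise ValueError(f"{name} must lie in [0, 1{top}, got {v!r}")


def make_responsive(m1: float, m2: float, d1: float, d2: float) -> StrategyPair:
    """Responsive (environment-sensing) switcher.

    Only active offspring (mean ``m1``) while the environment is
    healthy, only dormant offspring (mean ``m2``) while it is harsh;
    dormant individuals wake in good times and persist (death prob
    ``d_e``) in bad times.
    """
    if not (m1 > 0 and m2 > 0):
        raise ValueError("offspring means m1, m2 must be > 0")
    _check_prob("d1", d1)
    _check_prob("d2", d2)
    M1 = np.array([[m1, 0.0], [1.0 - d1, 0.0]])
    M2 = np.array([[0.0, m2], [0.0, 1.0 - d2]])
    return StrategyPair(M1, M2, "responsive", "responsive",
                        dict(m1=m1, m2=m2, d1=d1, d2=d2))


def make_preliminary(m1: float, m2: float, d1: float, d2: float) -> StrategyPair:
    """Preliminary (anticipatory) switcher: the mirror of responsive.

    Invests in dormant offspring during good times and in active
    offspring during harsh times, anticipating the next change.
    """
    if not (m1 > 0 and m2 > 0):
        raise ValueError("offspring means m1, m2 must be > 0")
    _check_prob("d1", d1)
    _check_prob("d2", d2)
    M1 = np.array([[0.0, m1], [0.0, 1.0 - d1]])
    M2 = np.array([[m2, 0.0], [1.0 - d2, 0.0]])
    return StrategyPair(M1, M2, "preliminary", "preliminary",
                        dict(m1=m1, m2=m2, d1=d1, d2=d2))


def make_stochastic(
    m_a: float,
    m_d: float,
    alpha: float,
    w1: float,
    w2: float,
    d1: float,
    d2: float,
) -> StrategyPair:
    """Stochastic (spontaneous) switcher: environment-blind bet hedging.

    Active parents allocate means ``(m_a, m_d)`` to active/dormant
    offspring regardless of the environment; harsh conditions scale the
    whole allocation by ``alpha in [0, 1)``.
    """
    if not (m_a > 0 and m_d > 0):
        raise ValueError("offspring means m_a, m_d must be > 0")
    _check_prob("alpha", alpha)
    for name, w, d in (("1", w1, d1), ("2", w2, d2)):
        _check_prob(f"w{name}", w, closed_top=True)
        _check_prob(f"d{name}", d, closed_top=True)
        if w + d > 1.0 + 1e-12:
            raise ValueError(f"w{name} + d{name} must be <= 1, got {w + d}")
    M1 = np.array([[m_a, m_d], [w1, 1.0 - w1 - d1]])
    M2 = np.array([[alpha * m_a, alpha * m_d], [w2, 1.0 - w2 - d2]])
    return StrategyPair(M1, M2, "stochastic", "stochastic",
                        dict(m_a=m_a, m_d=m_d, alpha=alpha,
                             w1=w1, w2=w2, d1=d1, d2=d2))


def make_sleepless(m1: float, m2: float, d1: float = 0.2, d2: float = 0.2) -> StrategyPair:
    """The 1-type process without dormancy, embedded as a 2x2 pair.

    ``M(e) = [[m_e, 0], [1-d_e, 0]]`` is reducible (no dormant offspring
    is ever produced), so the exponent reduces to the scalar rule and is
    independent of ``d1, d2``; the dormant row exists only to make fair
    comparison with dormancy strategies well defined.
    """
    if not (m1 > 0 and m2 > 0):
        raise ValueError("offspring means m1, m2 must be > 0")
    _check_prob("d1", d1)
    _check_prob("d2", d2)
    M1 = np.array([[m1, 0.0], [1.0 - d1, 0.0]])
    M2 = np.array([[m2, 0.0], [1.0 - d2, 0.0]])
    return StrategyPair(M1, M2, "sleepless", "sleepless",
                        dict(m1=m1, m2=m2, d1=d1, d2=d2), reducible=True)


def make_convex_combination(
    pre: StrategyPair,
    res: StrategyPair,
    q1: float,
    q2: float,
    label: str | None = None,
) -> StrategyPair:
    """Mixture strategy: each newborn follows the preliminary mechanism
    with probability ``q(e)`` and the responsive one otherwise.

    ``M_q(e) = q(e) * M_pre(e) + (1-q(e)) * M_res(e)``.  Under fair
    comparison of the ingredients the mixture stays rank <= 1 per
    matrix and its exponent remains exactly computable.
    """
    for name, q in (("q1", q1), ("q2", q2)):
        _check_prob(name, q, closed_top=True)
    M1 = q1 * pre.M1 + (1.0 - q1) * res.M1
    M2 = q2 * pre.M2 + (1.0 - q2) * res.M2
    if label is None:
        label = f"convex(q1={q1:g},q2={q2:g})"
    return StrategyPair(M1, M2, label, "convex", dict(q1=q1, q2=q2))


def make_general(M1: np.ndarray, M2: np.ndarray, label: str = "general") -> StrategyPair:
    """Wrap two arbitrary nonnegative 2x2 mean matrices as a strategy."""
    return StrategyPair(validate_mean_matrix(M1), validate_mean_matrix(M2),
                        label, "general")


def check_fair_comparison(
    a: StrategyPair,
    b: StrategyPair,
    gamma: CostWeight | float = 1.0,
    tol: float = FAIR_TOL,
) -> tuple[bool, dict]:
    """Check the (gamma-weighted) fair-comparison condition.

    Two dormancy strategies are comparable when, in each environment
    ``e``,

    (i)  the active-parent offspring budgets agree with dormant
         offspring priced at ``gamma`` active units:
         ``m_a^e + gamma*m_d^e`` equal, and
    (ii) the dormant death probabilities agree: ``d^e`` equal
         (equivalently, equal dormant row sums ``w^e + (1-w^e-d^e)``).

    At ``gamma = 1`` both conditions reduce to plain row-sum equality
    for every parent type.

    Returns ``(ok, diagnostics)`` where diagnostics maps
    ``(environment, parent_type)`` to the two budgets and their gap.
    """
    g = gamma.gamma if isinstance(gamma, CostWeight) else float(gamma)
    if not g > 0:
        raise ValueError(f"gamma must be > 0, got {g!r}")
    active_w = np.array([1.0, g])
    dormant_w = np.array([1.0, 1.0])  # compares survival 1 - d^e
    ok = True
    diag: dict[tuple[int, int], dict] = {}
    for e in (1, 2):
        for t, wvec in ((1, active_w), (2, dormant_w)):
            ra = float(a.matrix(e)[t - 1] @ wvec)
            rb = float(b.matrix(e)[t - 1] @ wvec)
            gap = abs(ra - rb)
            diag[(e, t)] = {"budget_a": ra, "budget_b": rb, "gap": gap}
            if gap > tol:
                ok = False
    return ok, diag


def rank_class(M: np.ndarray, tol: float = RANK_TOL) -> int:
    """Classify a nonzero mean matrix as rank 1 or rank 2.

    Rank 1 iff ``|det M| <= tol * (1 + ||M||_1^2)`` — a scale-aware
    near-singularity test (the strategy constructions of interest are
    exact rationals, so the default tolerance is tight).
    """
    M = validate_mean_matrix(M)
    norm1 = np.abs(M).sum()
    if norm1 == 0.0:
        raise ValueError("rank_class is undefined for the zero matrix")
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    return 1 if abs(det) <= tol * (1.0 + norm1**2) else 2
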