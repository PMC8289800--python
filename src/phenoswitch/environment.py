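"""Two-state Markov environment.

The environment alternates randomly between state 1 ("healthy") and
state 2 ("harsh").  From state 1 it switches to state 2 with probability
``s1``; from state 2 back to state 1 with probability ``s2``.  The chain
is started from its stationary law

    pi = (s2/(s1+s2), s1/(s1+s2)),

which makes the environment process stationary and ergodic as long as
``s1*s2 < 1`` (deterministic alternation ``s1 = s2 = 1`` is excluded).

States are encoded as the integers 1 and 2 throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EnvironmentParams",
    "transition_matrix",
    "stationary_distribution",
    "simulate_path",
]


@dataclass(frozen=True)
class EnvironmentParams:
    """Switching probabilities of the binary random environment.

    Parameters
    ----------
    s1 : float
        Probability of switching healthy -> harsh, in (0, 1].
    s2 : float
        Probability of switching harsh -> healthy, in (0, 1].

    Raises
    ------
    ValueError
        If a probability is outside (0, 1] or ``s1*s2 >= 1``.
    """

    s1: float
    s2: float

    def __post_init__(self) -> None:
        for name in ("s1", "s2"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v!r}")
        if self.s1 * self.s2 >= 1.0:
            raise ValueError(
                "s1*s2 must be < 1 (deterministic alternation is excluded), "
                f"got s1={self.s1}, s2={self.s2}"
            )


def transition_matrix(env: EnvironmentParams) -> np.ndarray:
    """Row-stochastic 2x2 transition matrix [[1-s1, s1], [s2, 1-s2]]."""
    return np.array([[1.0 - env.s1, env.s1], [env.s2, 1.0 - env.s2]])


def stationary_distribution(env: EnvironmentParams) -> np.ndarray:
    """Stationary law (s2, s1)/(s1+s2) of the environment chain."""
    z = env.s1 + env.s2
    return np.array([env.s2 / z, env.s1 / z])


def simulate_path(
    env: EnvironmentParams,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate a stationary environment path of length ``n``.

    The first state is drawn from the stationary distribution, subsequent
    states follow the transition matrix.  Returns an int array with
    values in {1, 2}.
    """
    if n < 1:
        raise ValueError(f"path length must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    path = np.empty(n, dtype=np.int64)
    pi1 = env.s2 / (env.s1 + env.s2)
    state = 1 if u[0] < pi1 else 2
    path[0] = state
    for k in range(1, n):
        if state == 1:
            if u[k] < env.s1:
                state = 2
        else:
            if u[k] < env.s2:
                state = 1
        path[k] = state
    return path


def _simulate_paths(
    env: EnvironmentParams,
    n: int,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized batch of stationary paths, shape (n_reps, n), values {1,2}.

    Internal helper shared by the Monte-Carlo exponent estimator and the
    population simulator.
    """
    pi1 = env.s2 / (env.s1 + env.s2)
    states = np.where(rng.random(n_reps) < pi1, 1, 2).astype(np.int8)
    out = np.empty((n_reps, n), dtype=np.int8)
    out[:, 0] = states
    for k in range(1, n):
        u = rng.random(n_reps)
        switch = np.where(states == 1, u < env.s1, u < env.s2)
        states = np.where(switch, 3 - states, states)
        out[:, k] = states
    return out
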