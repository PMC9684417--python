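"""Grey Wolf Optimizer for bounded continuous minimisation.

The pack's three best solutions — alpha, beta, delta — steer every
agent.  For agent position X and leader L with exploration coefficient
``a`` (linearly decaying from 2 to 0 over the run):

    A = 2 a r1 − a,         C = 2 r2            (r1, r2 ~ U[0,1] per dim)
    D_L = |C · L − X|,      X_L = L − A · D_L
    X(t+1) = (X_alpha + X_beta + X_delta) / 3

``|A| > 1`` pushes agents away from the leaders (exploration);
``|A| < 1`` pulls them in (exploitation).  C stays random throughout,
which keeps some exploration alive even in late iterations.

Implementation choices (the model leaves them open):

* r1 and r2 are drawn fresh per dimension, per leader, per agent,
  per iteration — maximal stochasticity;
* out-of-bounds positions are clipped component-wise to the box;
* leader ranking breaks ties by lowest agent index, so a fixed seed
  gives a bit-identical result;
* the best-ever alpha is retained even if the swarm later moves away,
  which makes the fitness history monotone non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["GWOConfig", "GWOResult", "decay_coefficient",
           "coefficient_vectors", "update_position", "optimize"]


class OptimizationError(RuntimeError):
    """Raised when the objective returns a non-finite value."""


@dataclass(frozen=True)
class GWOConfig:
    """Optimizer settings.

    ``n_agents`` and ``max_iter`` both default to 10, a budget that is
    already sufficient for the 3-dimensional template-scaling problems
    this package optimises.
    """

    lower_bounds: Sequence[float]
    upper_bounds: Sequence[float]
    n_agents: int = 10
    max_iter: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        lb = np.asarray(self.lower_bounds, dtype=float)
        ub = np.asarray(self.upper_bounds, dtype=float)
        object.__setattr__(self, "lower_bounds", lb)
        object.__setattr__(self, "upper_bounds", ub)
        if lb.shape != ub.shape or lb.ndim != 1 or lb.size < 1:
            raise ValueError("bounds must be 1-D vectors of equal length")
        if not np.all(lb < ub):
            raise ValueError("each lower bound must be strictly below its upper bound")
        if self.n_agents < 3:
            raise ValueError("need at least 3 agents (alpha, beta, delta)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    @property
    def dim(self) -> int:
        return int(np.asarray(self.lower_bounds).size)


@dataclass(frozen=True)
class GWOResult:
    """Best-ever alpha solution with its per-iteration fitness history."""

    best_position: np.ndarray
    best_fitness: float
    fitness_history: np.ndarray
    n_evals: int


def decay_coefficient(t: int, max_iter: int) -> float:
    """Exploration coefficient a(t) = 2 − 2t/max_iter, linear from 2 to 0."""
    if not 0 <= t <= max_iter:
        raise ValueError(f"iteration {t} outside [0, {max_iter}]")
    return 2.0 - (2.0 * t) / max_iter


def coefficient_vectors(decay_a: float, dim: int,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw the coefficient vectors A = 2·a·r1 − a and C = 2·r2.

    A is uniform on [−a, a] per component; C is uniform on [0, 2].
    Fresh r1, r2 on every call.
    """
    if not 0.0 <= decay_a <= 2.0:
        raise ValueError(f"decay coefficient {decay_a} outside [0, 2]")
    r1 = rng.uniform(size=dim)
    r2 = rng.uniform(size=dim)
    return 2.0 * decay_a * r1 - decay_a, 2.0 * r2


def update_position(x: np.ndarray,
                    leaders: tuple[np.ndarray, np.ndarray, np.ndarray],
                    decay_a: float,
                    rng: np.random.Generator) -> np.ndarray:
    """One hunting update: average of the three leader-guided candidates.

    Independent (A, C) pairs are drawn per leader, in alpha, beta, delta
    order.  The caller is responsible for clipping to bounds.
    """
    x = np.asarray(x, dtype=float)
    candidates = np.empty((3, x.size))
    for i, leader in enumerate(leaders):
        a_vec, c_vec = coefficient_vectors(decay_a, x.size, rng)
        d = np.abs(c_vec * leader - x)
        candidates[i] = leader - a_vec * d
    return candidates.mean(axis=0)


def optimize(objective: Callable[[np.ndarray], float],
             cfg: GWOConfig,
             rng: np.random.Generator | None = None,
             initial_positions: np.ndarray | None = None) -> GWOResult:
    """Minimise ``objective`` over the bounded box.

    Agents start uniformly in the box (optionally, the first rows of
    ``initial_positions`` override them — used for warm starts).  The
    saved alpha/beta/delta leaders are the three best solutions ever
    evaluated (ties broken by lowest agent index); each iteration moves
    every agent by :func:`update_position` towards them, clips to the
    box and re-evaluates, with the exploration coefficient following
    :func:`decay_coefficient`.

    Returns the best position ever evaluated.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lb, ub = np.asarray(cfg.lower_bounds), np.asarray(cfg.upper_bounds)
    dim = cfg.dim
    positions = rng.uniform(lb, ub, size=(cfg.n_agents, dim))
    if initial_positions is not None:
        given = np.atleast_2d(np.asarray(initial_positions, dtype=float))
        k = min(given.shape[0], cfg.n_agents)
        positions[:k] = np.clip(given[:k], lb, ub)

    def evaluate(pos: np.ndarray) -> np.ndarray:
        values = np.empty(pos.shape[0])
        for i, p in enumerate(pos):
            v = float(objective(p))
            if not np.isfinite(v):
                raise OptimizationError(
                    f"objective returned non-finite value {v} at {p}"
                )
            values[i] = v
        return values

    # alpha/beta/delta are the three best solutions ever evaluated;
    # scanning agents in index order with strict '<' breaks ties by
    # lowest agent index
    leader_fit = np.full(3, np.inf)
    leader_pos = np.zeros((3, dim))

    def absorb(pos: np.ndarray, values: np.ndarray) -> None:
        for i in range(pos.shape[0]):
            v = values[i]
            if v < leader_fit[0]:
                leader_fit[2], leader_pos[2] = leader_fit[1], leader_pos[1]
                leader_fit[1], leader_pos[1] = leader_fit[0], leader_pos[0]
                leader_fit[0], leader_pos[0] = v, pos[i].copy()
            elif v < leader_fit[1]:
                leader_fit[2], leader_pos[2] = leader_fit[1], leader_pos[1]
                leader_fit[1], leader_pos[1] = v, pos[i].copy()
            elif v < leader_fit[2]:
                leader_fit[2], leader_pos[2] = v, pos[i].copy()

    absorb(positions, evaluate(positions))
    n_evals = cfg.n_agents

    history = np.empty(cfg.max_iter)
    for t in range(1, cfg.max_iter + 1):
        leaders = (leader_pos[0].copy(), leader_pos[1].copy(),
                   leader_pos[2].copy())
        a_t = decay_coefficient(t, cfg.max_iter)
        for i in range(cfg.n_agents):
            positions[i] = np.clip(
                update_position(positions[i], leaders, a_t, rng), lb, ub
            )
        absorb(positions, evaluate(positions))
        n_evals += cfg.n_agents
        history[t - 1] = leader_fit[0]

    return GWOResult(leader_pos[0].copy(), float(leader_fit[0]), history,
                     n_evals)
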