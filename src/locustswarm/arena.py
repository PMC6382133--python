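"""The one-dimensional periodic arena and the asynchronous update sweep.

The world is a ring of W discrete blocks (periodic boundary conditions);
agents sit on blocks, move at one block per time-step, and can pass through
each other.  An agent perceives the *net flow* of conspecifics within its
sensory range r: the number of neighbours moving in its own direction minus
the number moving against it, clipped to {−2, …, +2}.  Together W and r set
the number B = W/(2r) of non-overlapping neighbourhoods, the effective
inverse density scale of the model.

One *sweep* (time-step) proceeds asynchronously: agents take their turns one
after another in a fixed order, so no neighbour changes direction while an
agent deliberates.  Each turn is percept → deliberation → action (possibly
flipping the heading) → reward.  The reward is R = 1 iff, after its own
action, the agent moves with the *strict* majority of its neighbours (ties
and isolated agents earn R = 0 by default).  In learning mode the agent's
memory is then updated; in fixed mode memories never change.  After all N
turns every agent advances one block along its heading (``move="per_sweep"``;
``move="per_turn"`` steps each agent right after its own turn instead).

The group's order parameter is the alignment z = (1/N) Σ_i σ_i ∈ [−1, +1].

The module exposes a per-swarm surface (:func:`sweep`, :func:`compute_percept`,
…) built on a batched core that advances many replicate swarms at once; the
batched core is what the transition-kernel estimator and the ensemble runner
use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .ps_agent import CONTINUE, AgentParams, HMatrix, a_index, make_neutral_memory

__all__ = [
    "WorldConfig",
    "AgentState",
    "SwarmState",
    "ring_distance",
    "compute_percept",
    "compute_reward",
    "sweep",
    "alignment",
    "init_swarm",
]


@dataclass(frozen=True)
class WorldConfig:
    """Geometry and population of the ring world.

    W: world size in blocks; r: sensory range in blocks; N: population size.
    Requires 2r < W so a neighbourhood never wraps onto itself.
    """

    W: int
    r: int
    N: int

    def __post_init__(self) -> None:
        for name in ("W", "r", "N"):
            v = getattr(self, name)
            if int(v) != v or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if 2 * self.r >= self.W:
            raise ValueError("need 2r < W (sensory window smaller than the ring)")

    @property
    def B(self) -> float:
        """Number of non-overlapping neighbourhoods, B = W / (2r)."""
        return self.W / (2 * self.r)


class AgentState(NamedTuple):
    """Read-only view of one agent within a swarm."""

    position: int
    heading: int
    memory: HMatrix
    params: AgentParams


@dataclass
class SwarmState:
    """Positions, headings and memories of all N agents at one time-step.

    Stored as flat arrays (positions ``(N,)`` int, headings ``(N,)`` ±1,
    memories ``(N, 5, 2)`` float) for fast vectorised sweeps; the agent
    order is fixed for the whole run and is the deliberation order.
    """

    positions: np.ndarray
    headings: np.ndarray
    memories: np.ndarray
    params: AgentParams
    t: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.headings = np.asarray(self.headings, dtype=np.int64)
        self.memories = np.asarray(self.memories, dtype=float)
        if not np.all(np.isin(self.headings, (-1, 1))):
            raise ValueError("headings must be ±1")
        if self.memories.shape != (self.N, 5, 2):
            raise ValueError("memories must have shape (N, 5, 2)")

    @property
    def N(self) -> int:
        return len(self.positions)

    def agent(self, i: int) -> AgentState:
        return AgentState(
            int(self.positions[i]),
            int(self.headings[i]),
            HMatrix(self.memories[i].copy()),
            self.params,
        )

    def copy(self) -> "SwarmState":
        return SwarmState(
            self.positions.copy(),
            self.headings.copy(),
            self.memories.copy(),
            self.params,
            self.t,
        )


# ---------------------------------------------------------------------------
# geometry, percepts, rewards


def ring_distance(x1, x2, W: int):
    """Shortest distance between blocks on the ring of size W."""
    x1 = np.asarray(x1)
    x2 = np.asarray(x2)
    if np.any(x1 < 0) or np.any(x1 >= W) or np.any(x2 < 0) or np.any(x2 >= W):
        raise ValueError(f"positions must lie in [0, {W})")
    d = np.abs(x1 - x2)
    d = np.minimum(d, W - d)
    return d if d.ndim else int(d)


def _neighbour_counts(swarm: SwarmState, i: int, cfg: WorldConfig) -> tuple[int, int]:
    """(n_same, n_opp) among agents within ring distance ≤ r of agent i."""
    d = ring_distance(swarm.positions, swarm.positions[i], cfg.W)
    mask = d <= cfg.r
    mask[i] = False
    n_same = int(np.sum(mask & (swarm.headings == swarm.headings[i])))
    return n_same, int(mask.sum()) - n_same


def compute_percept(swarm: SwarmState, i: int, cfg: WorldConfig) -> int:
    """Net relative flow around agent i, clipped to {−2, …, +2}.

    Counts every *other* agent within ring distance ≤ r (co-located agents
    included) and returns clamp(n_same − n_opp, −2, +2).
    """
    n_same, n_opp = _neighbour_counts(swarm, i, cfg)
    return int(np.clip(n_same - n_opp, -2, 2))


def compute_reward(
    swarm: SwarmState, i: int, cfg: WorldConfig, reward_ties: bool = False
) -> int:
    """Majority-alignment reward for agent i *after* its action this turn.

    R = 1 iff strictly more neighbours share the agent's current heading
    than oppose it.  Ties and isolated agents earn R = 0 unless
    ``reward_ties`` is set (which rewards exact ties with ≥1 neighbour).
    """
    n_same, n_opp = _neighbour_counts(swarm, i, cfg)
    if n_same > n_opp:
        return 1
    if reward_ties and n_same + n_opp > 0 and n_same == n_opp:
        return 1
    return 0


def alignment(swarm: SwarmState) -> float:
    """Order parameter z = (1/N) Σ_i σ_i ∈ [−1, +1]."""
    return float(swarm.headings.mean())


# ---------------------------------------------------------------------------
# the batched sweep core
#
# Advances R replicate swarms simultaneously.  All arrays have a leading
# replicate axis: positions/headings (R, N), memories (R, N, 5, 2).  A single
# RNG stream is consumed in turn order (one uniform block of R draws per
# agent turn), so an R=1 call is byte-for-byte a plain single-swarm sweep.


def _sweep_batch(
    positions: np.ndarray,
    headings: np.ndarray,
    cfg: WorldConfig,
    rng: np.random.Generator,
    *,
    memories: np.ndarray | None = None,
    p_continue: np.ndarray | None = None,
    learning: bool = False,
    gamma: float = 0.0,
    move: str = "per_sweep",
    reward_ties: bool = False,
    events: list | None = None,
) -> None:
    """One asynchronous sweep, in place.

    Either ``memories`` (per-agent h-matrices, required in learning mode) or
    ``p_continue`` (shared fixed policy: P(a=+1|s) for s = −2..+2) must be
    given.  ``events``, if a list, receives one (i, s, a, R) tuple of arrays
    per agent turn.
    """
    if move not in ("per_sweep", "per_turn"):
        raise ValueError(f"move must be 'per_sweep' or 'per_turn', got {move!r}")
    R, N = positions.shape
    ridx = np.arange(R)
    one_minus_gamma = 1.0 - gamma
    for i in range(N):
        d = np.abs(positions - positions[:, i : i + 1])
        np.minimum(d, cfg.W - d, out=d)
        nb = d <= cfg.r
        nb[:, i] = False
        same = nb & (headings == headings[:, i : i + 1])
        n_same = same.sum(axis=1)
        n_tot = nb.sum(axis=1)
        n_opp = n_tot - n_same
        s = np.clip(n_same - n_opp, -2, 2)
        if memories is not None:
            rows = memories[ridx, i, s + 2, :]  # (R, 2)
            p_cont = rows[:, 1] / rows.sum(axis=1)
        else:
            p_cont = p_continue[s + 2]
        a = np.where(rng.random(R) < p_cont, 1, -1)
        headings[:, i] *= a
        n_same_after = np.where(a == 1, n_same, n_opp)
        n_opp_after = n_tot - n_same_after
        if reward_ties:
            rew = (n_same_after >= n_opp_after) & (n_tot > 0)
        else:
            rew = n_same_after > n_opp_after
        if learning:
            mem_i = memories[:, i]  # (R, 5, 2) view
            np.multiply(mem_i - 1.0, one_minus_gamma, out=mem_i)
            mem_i += 1.0
            memories[ridx, i, s + 2, (a + 1) // 2] += rew
        if events is not None:
            events.append((i, s.copy(), a, rew.astype(np.int64)))
        if move == "per_turn":
            positions[:, i] = (positions[:, i] + headings[:, i]) % cfg.W
    if move == "per_sweep":
        positions += headings
        positions %= cfg.W


def sweep(
    swarm: SwarmState,
    cfg: WorldConfig,
    rng: np.random.Generator,
    *,
    move: str = "per_sweep",
    reward_ties: bool = False,
    events: list | None = None,
) -> SwarmState:
    """Apply one full asynchronous time-step and return the successor state.

    Agents deliberate in index order; learning-mode agents update their
    memories with the reinforcement/forgetting rule after their own turn.
    The input state is not modified.  If ``events`` is a list it receives
    one ``(t, agent_id, percept, action, reward)`` tuple per turn.
    """
    out = swarm.copy()
    learning = swarm.params.mode == "learning"
    gamma = swarm.params.gamma if learning and swarm.params.gamma is not None else 0.0
    raw_events: list | None = [] if events is not None else None
    _sweep_batch(
        out.positions.reshape(1, -1),
        out.headings.reshape(1, -1),
        cfg,
        rng,
        memories=out.memories.reshape(1, out.N, 5, 2),
        learning=learning,
        gamma=gamma,
        move=move,
        reward_ties=reward_ties,
        events=raw_events,
    )
    out.t = swarm.t + 1
    if events is not None:
        for i, s, a, rew in raw_events:
            events.append((out.t, i, int(s[0]), int(a[0]), int(rew[0])))
    return out


def init_swarm(
    cfg: WorldConfig,
    params: AgentParams,
    rng: np.random.Generator,
    policy: HMatrix | None = None,
) -> SwarmState:
    """Fresh swarm: positions i.i.d. uniform over blocks, headings i.i.d. ±1.

    Fixed mode copies ``policy`` (default: the d-disposition from ``params``)
    into every agent; learning mode starts every agent from the neutral
    memory (plus inertia on the (0, +1) edge if requested).
    """
    from .ps_agent import make_fixed_disposition  # local: avoids cycle at import

    positions = rng.integers(0, cfg.W, size=cfg.N)
    headings = rng.integers(0, 2, size=cfg.N) * 2 - 1
    if policy is None:
        if params.mode == "fixed":
            if params.d is None:
                raise ValueError("fixed mode needs a decisiveness d or an explicit policy")
            policy = make_fixed_disposition(params.d, params.inertia)
        else:
            policy = make_neutral_memory()
            if params.inertia > 0:
                h = policy.h.copy()
                h[2, a_index(CONTINUE)] = 1.0 + params.inertia
                policy = HMatrix(h)
    memories = np.broadcast_to(policy.h, (cfg.N, 5, 2)).copy()
    return SwarmState(positions, headings, memories, params, t=0)
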