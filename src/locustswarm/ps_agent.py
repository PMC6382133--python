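"""Two-layer projective-simulation (PS) agents for the locust alignment task.

A PS agent stores its experience in an *episodic memory*: a bipartite clip
network whose first layer holds the five percepts s ∈ {−2, −1, 0, +1, +2}
(the net flow of neighbours relative to the agent, clipped at ±2) and whose
second layer holds the two actions a ∈ {−1 (turn around), +1 (continue)}.
Each percept→action edge carries a real-valued weight h(s, a) ≥ 1, so the
whole memory is a 5 × 2 matrix of h-values.

Deliberation is a single hop of a random walk over this network: given a
percept s, the agent chooses action a with probability

    P(a | s) = h(s, a) / Σ_a' h(s, a'),

i.e. the h-values are simply normalised per row.  Learning combines
reinforcement of the edge actually used with exponential forgetting toward
the neutral value 1:

    h'(s, a) − 1 = (1 − γ) (h(s, a) − 1) + R · [edge (s, a) was used],

with reward R ≥ 0 (here R ∈ {0, 1}) and forgetting rate γ ∈ [0, 1].
Forgetting damps the h-values toward 1 — never below — which keeps the
policy well defined and lets agents track changing environments.

Agents with *fixed dispositions* emulate a conventional self-propelled
particle model: the h-matrix is frozen at a one-parameter family where a
"decisiveness" d controls how strongly the agent follows the local majority
(see :func:`make_fixed_disposition`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PERCEPTS",
    "ACTIONS",
    "TURN",
    "CONTINUE",
    "ParameterError",
    "HMatrix",
    "AgentParams",
    "make_neutral_memory",
    "make_fixed_disposition",
    "action_probabilities",
    "sample_action",
    "update_memory",
    "average_policy",
]

#: Percept alphabet: net flow of neighbours relative to the agent, clipped.
PERCEPTS = (-2, -1, 0, 1, 2)
#: Action alphabet: turn around (−1) or continue in the same direction (+1).
ACTIONS = (-1, 1)
TURN = -1
CONTINUE = 1

_H_MIN_TOL = 1e-9  # slack for floating-point drift below the h >= 1 floor


class ParameterError(ValueError):
    """Raised for invalid agent parameters (negative d, γ outside [0,1], ...)."""


def s_index(s: int) -> int:
    """Row index of percept ``s`` in the 5 × 2 h-matrix."""
    if s not in PERCEPTS:
        raise IndexError(f"unknown percept {s!r}; expected one of {PERCEPTS}")
    return int(s) + 2


def a_index(a: int) -> int:
    """Column index of action ``a`` (−1 → 0, +1 → 1)."""
    if a not in ACTIONS:
        raise IndexError(f"unknown action {a!r}; expected one of {ACTIONS}")
    return (int(a) + 1) // 2


@dataclass
class HMatrix:
    """The 5 × 2 table of h-values of a two-layer PS memory.

    Rows are indexed by percept s = −2 … +2, columns by action a = −1, +1.
    All entries are ≥ 1 (the update rule damps toward 1, never below).
    """

    h: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        if h.shape != (5, 2):
            raise ParameterError(f"h-matrix must be 5x2, got shape {h.shape}")
        if np.any(h < 1.0 - _H_MIN_TOL):
            raise ParameterError("h-values must be >= 1")
        self.h = h

    # -- deliberation ------------------------------------------------------
    def action_probabilities(self, s: int) -> np.ndarray:
        """Response probabilities ``(P(a=−1|s), P(a=+1|s))`` for percept ``s``."""
        row = self.h[s_index(s)]
        return row / row.sum()

    def probabilities(self) -> np.ndarray:
        """Full 5 × 2 table of response probabilities (rows sum to 1)."""
        return self.h / self.h.sum(axis=1, keepdims=True)

    # -- bookkeeping -------------------------------------------------------
    def copy(self) -> "HMatrix":
        return HMatrix(self.h.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HMatrix):
            return NotImplemented
        return np.array_equal(self.h, other.h)

    def allclose(self, other: "HMatrix", **kwargs) -> bool:
        return np.allclose(self.h, other.h, **kwargs)

    # -- serialisation -----------------------------------------------------
    def to_csv(self, path_or_buf=None) -> str | None:
        """Write the matrix as a labelled CSV block (rows s=−2..+2)."""
        lines = ["s,a=-1,a=+1"]
        for s in PERCEPTS:
            row = self.h[s_index(s)]
            lines.append(f"{s},{float(row[0])!r},{float(row[1])!r}")
        text = "\n".join(lines) + "\n"
        if path_or_buf is None:
            return text
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)
        return None

    @classmethod
    def from_csv(cls, path_or_buf) -> "HMatrix":
        if isinstance(path_or_buf, str) and "\n" in path_or_buf:
            fh = io.StringIO(path_or_buf)
        elif hasattr(path_or_buf, "read"):
            fh = path_or_buf
        else:
            fh = open(path_or_buf)
        try:
            header = fh.readline().strip()
            if header != "s,a=-1,a=+1":
                raise ValueError(f"unexpected h-matrix header {header!r}")
            h = np.ones((5, 2))
            for line in fh:
                if not line.strip():
                    continue
                s_str, h_turn, h_cont = line.strip().split(",")
                h[s_index(int(s_str))] = (float(h_turn), float(h_cont))
        finally:
            fh.close()
        return cls(h)


@dataclass(frozen=True)
class AgentParams:
    """Static (meta-)parameters of an agent.

    mode
        ``"fixed"`` — the h-matrix is frozen (self-propelled-particle limit);
        ``"learning"`` — the h-matrix evolves under reinforcement/forgetting.
    d
        Decisiveness of the fixed disposition (fixed mode only), d ≥ 0.
    gamma
        Forgetting rate γ ∈ [0, 1] (learning mode only).
    inertia
        Optional bias ι ≥ 0 toward continuing at zero net flow,
        h(0, +1) = 1 + ι, so that P(a=+1 | s=0) > 1/2.
    """

    mode: str = "fixed"
    d: float | None = None
    gamma: float | None = None
    inertia: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "learning"):
            raise ParameterError(f"mode must be 'fixed' or 'learning', got {self.mode!r}")
        if self.d is not None and self.d < 0:
            raise ParameterError("decisiveness d must be >= 0")
        if self.gamma is not None and not (0.0 <= self.gamma <= 1.0):
            raise ParameterError("forgetting gamma must lie in [0, 1]")
        if self.inertia < 0:
            raise ParameterError("inertia must be >= 0")


# ---------------------------------------------------------------------------
# constructors


def make_neutral_memory() -> HMatrix:
    """Neutral disposition: all h(s, a) = 1, so every response is 50/50."""
    return HMatrix(np.ones((5, 2)))


def make_fixed_disposition(d: float, inertia: float = 0.0) -> HMatrix:
    """Pre-programmed disposition for the alignment task.

    h(+2,+1) = h(−2,−1) = 1 + d,  h(+1,+1) = h(−1,−1) = 1 + d/2, all other
    entries 1.  The single decisiveness d ≥ 0 controls how strongly the agent
    keeps its direction when aligned with neighbours (s > 0) and turns around
    when facing opposition (s < 0).  An optional inertia ι > 0 additionally
    sets h(0,+1) = 1 + ι, biasing the agent toward continuing at zero net flow.
    """
    if d < 0:
        raise ParameterError("decisiveness d must be >= 0")
    if inertia < 0:
        raise ParameterError("inertia must be >= 0")
    h = np.ones((5, 2))
    h[s_index(+2), a_index(CONTINUE)] = 1.0 + d
    h[s_index(-2), a_index(TURN)] = 1.0 + d
    h[s_index(+1), a_index(CONTINUE)] = 1.0 + d / 2.0
    h[s_index(-1), a_index(TURN)] = 1.0 + d / 2.0
    if inertia > 0:
        h[s_index(0), a_index(CONTINUE)] = 1.0 + inertia
    return HMatrix(h)


# ---------------------------------------------------------------------------
# deliberation and update


def action_probabilities(hmatrix: HMatrix, s: int) -> np.ndarray:
    """Normalised response probabilities ``(P(−1|s), P(+1|s))`` for percept s."""
    return hmatrix.action_probabilities(s)


def sample_action(probabilities, rng: np.random.Generator) -> int:
    """Draw an action from ``(P(−1), P(+1))`` using one uniform variate.

    The convention (a = +1 iff u < P(+1)) matches the vectorised simulation
    core, so single-agent and swarm runs consume the RNG stream identically.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.shape != (2,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ParameterError(f"invalid probability pair {probabilities!r}")
    return CONTINUE if rng.random() < p[a_index(CONTINUE)] else TURN


def update_memory(
    hmatrix: HMatrix, used_edge: tuple[int, int], R: float, gamma: float
) -> HMatrix:
    """One reinforcement/forgetting step after an interaction.

    Every edge is damped toward 1 by the factor (1 − γ); the edge actually
    used in the deliberation additionally receives the reward R.  Returns a
    new :class:`HMatrix`; the input is left untouched.
    """
    if R < 0:
        raise ParameterError("reward must be >= 0 (the model uses R in {0, 1})")
    if not (0.0 <= gamma <= 1.0):
        raise ParameterError("forgetting gamma must lie in [0, 1]")
    s, a = used_edge
    h = 1.0 + (1.0 - gamma) * (hmatrix.h - 1.0)
    h[s_index(s), a_index(a)] += R
    return HMatrix(h)


def average_policy(memories, method: str = "h") -> HMatrix:
    """Ensemble-averaged policy over a collection of memories.

    ``method="h"`` (default) averages the h-values entry-wise — h is the
    model's native state.  ``method="probability"`` averages the response
    probabilities instead and re-embeds them as an h-matrix with row minimum
    1 (ratios preserved, so the averaged probabilities are reproduced).
    """
    mats = [m.h if isinstance(m, HMatrix) else np.asarray(m, float) for m in memories]
    if not mats:
        raise ValueError("average_policy needs a non-empty collection of memories")
    if method == "h":
        return HMatrix(np.mean(mats, axis=0))
    if method == "probability":
        probs = np.mean([m / m.sum(axis=1, keepdims=True) for m in mats], axis=0)
        scale = np.clip(probs.min(axis=1, keepdims=True), 1e-12, None)
        return HMatrix(probs / scale)
    raise ParameterError(f"unknown averaging method {method!r}")
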