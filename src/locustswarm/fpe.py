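"""Collective-level description: transition kernels, drift/diffusion, fixed points.

The group alignment z = (1/N) Σ σ_i evolves, over one sweep, according to a
Markov kernel P(z'|z) on the grid {(2m − N)/N : m = 0..N}.  On longer time
scales the probability density P(z, t) obeys a Fokker–Planck equation

    ∂_t P = −∂_z [F(z) P] + ∂_z² [D(z) P],

whose coefficients follow from the kernel as Kramers–Moyal conditional
moments (time unit = one sweep):

    F(z) = E[z' − z | z],          D(z) = ½ E[(z' − z − F(z))² | z].

Zeros of the drift F are fixed points of the collective dynamics; a zero
with dF/dz < 0 is an attractor.  The module provides three routes to the
curves:

* ``estimate_transition_kernel`` + ``km_from_kernel`` — model-exact
  Monte-Carlo estimate from single sweeps of swarms conditioned on z;
* ``meanfield_drift_diffusion`` — closed-form computation that treats each
  agent's turn against an i.i.d. background: neighbour count
  k ~ Binomial(N−1, 1/B), neighbour headings i.i.d. +1 with probability
  (1 + z)/2, so within-sweep sequential feedback is ignored;
* ``empirical_km`` — binned increments of a long simulated trajectory.

For decisiveness d = 0 all three reduce to the closed forms F(z) = −z and
D(z) = 1/(2N) (every post-turn heading is uniform ±1, independent of z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .arena import SwarmState, WorldConfig, _sweep_batch
from .ps_agent import AgentParams, HMatrix, ParameterError

__all__ = [
    "z_grid",
    "TransitionKernel",
    "DriftDiffusionCurves",
    "FixedPoint",
    "FixedPointSet",
    "sample_conditioned_swarm",
    "estimate_transition_kernel",
    "km_from_kernel",
    "meanfield_drift_diffusion",
    "empirical_km",
    "find_fixed_points",
]


def z_grid(N: int) -> np.ndarray:
    """The N + 1 attainable alignment values {(2m − N)/N : m = 0..N}."""
    return (2.0 * np.arange(N + 1) - N) / N


@dataclass
class TransitionKernel:
    """Monte-Carlo estimate of the one-sweep kernel P(z'|z) on the z grid."""

    grid: np.ndarray
    P: np.ndarray  # (G, G), row-stochastic
    counts: np.ndarray  # samples per row

    def __post_init__(self) -> None:
        rowsums = self.P.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise ValueError("kernel rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        """Long format ``z,zprime,p`` (zero-probability entries included)."""
        g = len(self.grid)
        return pd.DataFrame(
            {
                "z": np.repeat(self.grid, g),
                "zprime": np.tile(self.grid, g),
                "p": self.P.ravel(),
            }
        )


@dataclass
class DriftDiffusionCurves:
    """Drift F(z) and diffusion D(z) per sweep, with estimation metadata."""

    z: np.ndarray
    F: np.ndarray
    D: np.ndarray
    method: str  # "meanfield" | "kernel" | "empirical"
    se_F: np.ndarray | None = None
    se_D: np.ndarray | None = None
    n: np.ndarray | None = None  # samples behind each grid point

    def __post_init__(self) -> None:
        if np.any(self.D < -1e-12) or not np.all(np.isfinite(self.F)):
            raise ValueError("D must be >= 0 and F finite")

    def to_frame(self) -> pd.DataFrame:
        g = len(self.z)
        nan = np.full(g, np.nan)
        return pd.DataFrame(
            {
                "z": self.z,
                "F": self.F,
                "D": self.D,
                "se_F": self.se_F if self.se_F is not None else nan,
                "se_D": self.se_D if self.se_D is not None else nan,
                "method": [self.method] * g,
            }
        )


@dataclass(frozen=True)
class FixedPoint:
    z0: float
    slope: float
    stability: str  # "stable" | "unstable"
    low_confidence: bool = False


@dataclass
class FixedPointSet:
    """Zeros of the drift, sorted by location; stable iff dF/dz < 0."""

    points: list[FixedPoint] = field(default_factory=list)
    degenerate: bool = False  # F identically zero: every z is a fixed point

    def __iter__(self):
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def stable(self) -> list[FixedPoint]:
        return [p for p in self.points if p.stability == "stable"]

    def unstable(self) -> list[FixedPoint]:
        return [p for p in self.points if p.stability == "unstable"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.z0, p.slope, p.stability) for p in self.points],
            columns=["z0", "slope", "stability"],
        )


# ---------------------------------------------------------------------------
# conditioned sampling and the Monte-Carlo kernel


def _conditioned_headings(
    z: float, N: int, n_rows: int, rng: np.random.Generator
) -> np.ndarray:
    n_plus = (1.0 + z) * N / 2.0
    if abs(n_plus - round(n_plus)) > 1e-9:
        raise ParameterError(f"z={z} is not on the alignment grid for N={N}")
    base = np.where(np.arange(N) < round(n_plus), 1, -1)
    return rng.permuted(np.broadcast_to(base, (n_rows, N)), axis=1).astype(np.int64)


def sample_conditioned_swarm(
    z: float, cfg: WorldConfig, policy: HMatrix, rng: np.random.Generator
) -> SwarmState:
    """A random swarm with alignment exactly z: headings a random assignment
    of N(1+z)/2 agents to +1, positions i.i.d. uniform, all agents frozen at
    ``policy``."""
    headings = _conditioned_headings(z, cfg.N, 1, rng)[0]
    positions = rng.integers(0, cfg.W, size=cfg.N)
    memories = np.broadcast_to(policy.h, (cfg.N, 5, 2)).copy()
    # conditioned sampling is defined for the fixed-policy (SPP) limit
    d_eff = float(policy.h[4, 1] - 1.0)
    params = AgentParams(mode="fixed", d=d_eff)
    return SwarmState(positions, headings, memories, params, t=0)


def estimate_transition_kernel(
    cfg: WorldConfig,
    policy: HMatrix,
    n_samples: int,
    rng: np.random.Generator,
    *,
    move: str = "per_sweep",
    reward_ties: bool = False,
    batch_size: int = 20000,
) -> TransitionKernel:
    """Monte-Carlo estimate of P(z'|z): for each grid z, draw ``n_samples``
    conditioned swarms, apply one sweep (fixed policy, no learning) and
    histogram the resulting z'."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    N = cfg.N
    grid = z_grid(N)
    P = np.zeros((N + 1, N + 1))
    p_continue = policy.h[:, 1] / policy.h.sum(axis=1)
    for m, z in enumerate(grid):
        remaining = n_samples
        counts = np.zeros(N + 1)
        while remaining > 0:
            rows = min(remaining, batch_size)
            headings = _conditioned_headings(z, N, rows, rng)
            positions = rng.integers(0, cfg.W, size=(rows, N))
            _sweep_batch(
                positions,
                headings,
                cfg,
                rng,
                p_continue=p_continue,
                move=move,
                reward_ties=reward_ties,
            )
            m_prime = (headings.sum(axis=1) + N) // 2
            counts += np.bincount(m_prime, minlength=N + 1)
            remaining -= rows
        P[m] = counts / n_samples
    return TransitionKernel(grid, P, np.full(N + 1, n_samples))


def km_from_kernel(kernel: TransitionKernel) -> DriftDiffusionCurves:
    """Kramers–Moyal coefficients of the kernel: F(z) = E[Δz|z] and
    D(z) = ½ Var[Δz|z], per sweep, with Monte-Carlo standard errors."""
    if np.any(kernel.counts < 1):
        raise ValueError("kernel has empty rows")
    grid = kernel.grid
    mean_next = kernel.P @ grid
    F = mean_next - grid
    dev = grid[None, :] - mean_next[:, None]
    var = np.einsum("ij,ij->i", kernel.P, dev**2)
    D = 0.5 * var
    n = kernel.counts.astype(float)
    se_F = np.sqrt(var / np.maximum(n, 1))
    se_D = D * np.sqrt(2.0 / np.maximum(n - 1, 1))
    return DriftDiffusionCurves(grid, F, np.maximum(D, 0.0), "kernel", se_F, se_D, n)


# ---------------------------------------------------------------------------
# mean-field computation


def meanfield_drift_diffusion(
    N: int, B: float, policy: HMatrix, *, central: bool = True
) -> DriftDiffusionCurves:
    """Closed-form drift and diffusion from the individual-level rules.

    Each agent's turn is evaluated against an independent background drawn
    from the current alignment: it has k ~ Binomial(N−1, 1/B) neighbours
    whose headings are i.i.d. +1 with probability (1 + z)/2.  The percept is
    s = clamp(σ (2 n₊ − k), −2, +2) for focal heading σ, and the flip
    probability q(σ, z) = Σ_s P(s|σ, z) P(a = −1|s) follows from the policy.
    Then

        E[z'] = ((1+z)/2)(1 − 2 q(+1,z)) − ((1−z)/2)(1 − 2 q(−1,z)),
        F(z)  = E[z'] − z,
        D(z)  = Var[z'] / 2,  Var[z'] = (1/N)(1 − ⟨(1 − 2q)²⟩),

    with ⟨·⟩ the σ-average weighted by (1 ± z)/2.  All sums are exact (finite
    binomial support).  Within-sweep sequential updating is ignored; the MC
    kernel is the model-exact reference.  ``central=False`` uses the
    non-central second moment E[(z' − z)²]/2 instead (differs by F²/2).
    """
    if int(N) != N or N < 2:
        raise ParameterError("N must be an integer >= 2")
    if B <= 0:
        raise ParameterError("B must be positive")
    N = int(N)
    p_turn = policy.h[:, 0] / policy.h.sum(axis=1)  # P(a=−1 | s), s=−2..+2
    k_vals = np.arange(N)  # neighbour count 0..N−1
    pk = stats.binom.pmf(k_vals, N - 1, 1.0 / B)
    grid = z_grid(N)
    F = np.empty(N + 1)
    D = np.empty(N + 1)
    for gi, z in enumerate(grid):
        p_plus = (1.0 + z) / 2.0
        q = {}
        for sigma in (1, -1):
            total = 0.0
            for k in k_vals:
                n_up = np.arange(k + 1)
                w = stats.binom.pmf(n_up, k, p_plus)
                s = np.clip(sigma * (2 * n_up - k), -2, 2)
                total += pk[k] * float(w @ p_turn[s + 2])
            q[sigma] = total
        keep_p = 1.0 - 2.0 * q[1]   # E[σ' | σ=+1]
        keep_m = 1.0 - 2.0 * q[-1]  # −E[σ' | σ=−1] sign handled below
        mean_next = p_plus * keep_p - (1.0 - p_plus) * keep_m
        F[gi] = mean_next - z
        mean_sq = p_plus * keep_p**2 + (1.0 - p_plus) * keep_m**2
        var = (1.0 - mean_sq) / N
        D[gi] = var / 2.0 if central else (var + F[gi] ** 2) / 2.0
    return DriftDiffusionCurves(grid, F, D, "meanfield")


# ---------------------------------------------------------------------------
# empirical estimate from trajectories


def empirical_km(
    z_series, burn_in: int = 0, *, N: int | None = None, min_samples: int = 10
) -> DriftDiffusionCurves:
    """Drift/diffusion from binned one-step increments of a trajectory.

    ``z_series`` may be a :class:`~locustswarm.engine.TrajectoryRecord` or a
    plain array.  The series after ``burn_in`` is grouped by the (exact)
    grid value of z_t; per bin, F is the mean and D half the variance of
    z_{t+1} − z_t.  Bins with fewer than ``min_samples`` increments keep
    their estimate but are reported with n below the threshold.
    """
    z = np.asarray(getattr(z_series, "z", z_series), dtype=float)
    if len(z) - burn_in < 2:
        raise ValueError("need at least two post-burn-in points")
    z = z[burn_in:]
    if N is None:
        cfg = getattr(z_series, "config", None)
        if cfg is not None:
            N = cfg.N
        else:
            # infer N from the grid spacing actually visited
            steps = np.unique(np.round(np.abs(np.diff(np.unique(z))), 12))
            steps = steps[steps > 0]
            if steps.size:
                N = int(round(2.0 / steps.min()))
            else:  # constant trajectory: any grid containing the value works
                N = max(int(round(2.0 / max(abs(z[0]), 1e-12))), 2) if z[0] != 0 else 2
    grid = z_grid(N)
    idx = np.clip(np.round((z[:-1] + 1.0) * N / 2.0).astype(int), 0, N)
    dz = np.diff(z)
    F = np.full(N + 1, np.nan)
    D = np.full(N + 1, np.nan)
    se_F = np.full(N + 1, np.nan)
    n = np.bincount(idx, minlength=N + 1).astype(float)
    for m in np.unique(idx):
        vals = dz[idx == m]
        F[m] = vals.mean()
        D[m] = 0.5 * vals.var()
        se_F[m] = vals.std() / np.sqrt(len(vals)) if len(vals) > 1 else np.inf
    visited = ~np.isnan(F)
    return DriftDiffusionCurves(
        grid[visited],
        F[visited],
        D[visited],
        "empirical",
        se_F[visited],
        None,
        n[visited],
    )


# ---------------------------------------------------------------------------
# fixed points


def _centered_slope(z: np.ndarray, F: np.ndarray, i: int) -> float:
    lo = max(i - 1, 0)
    hi = min(i + 1, len(z) - 1)
    return float((F[hi] - F[lo]) / (z[hi] - z[lo]))


def find_fixed_points(
    curves: DriftDiffusionCurves, *, se_factor: float = 2.0
) -> FixedPointSet:
    """Zeros of the drift, by sign change + linear interpolation on the grid.

    Stability follows the slope sign (stable iff dF/dz < 0).  For Monte-Carlo
    curves, a root whose |F| stays below ``se_factor`` standard errors across
    its neighbourhood is flagged low-confidence.  An identically zero drift
    is degenerate (every z is marginal) and yields an empty, flagged set.
    """
    z, F = np.asarray(curves.z, float), np.asarray(curves.F, float)
    if np.all(F == 0.0):
        return FixedPointSet([], degenerate=True)
    pts: list[FixedPoint] = []

    def low_conf(i: int) -> bool:
        if curves.se_F is None:
            return False
        sl = slice(max(i - 2, 0), min(i + 3, len(z)))
        return bool(np.all(np.abs(F[sl]) < se_factor * curves.se_F[sl]))

    for i in range(len(z) - 1):
        if F[i] == 0.0:
            pts.append(
                FixedPoint(float(z[i]), _centered_slope(z, F, i), "", low_conf(i))
            )
        elif F[i] * F[i + 1] < 0.0:
            slope = float((F[i + 1] - F[i]) / (z[i + 1] - z[i]))
            z0 = float(z[i] - F[i] / slope)
            pts.append(FixedPoint(z0, slope, "", low_conf(i)))
    if F[-1] == 0.0:
        i = len(z) - 1
        pts.append(FixedPoint(float(z[i]), _centered_slope(z, F, i), "", low_conf(i)))
    pts = [
        FixedPoint(p.z0, p.slope, "stable" if p.slope < 0 else "unstable", p.low_confidence)
        for p in pts
    ]
    pts.sort(key=lambda p: p.z0)
    return FixedPointSet(pts)
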