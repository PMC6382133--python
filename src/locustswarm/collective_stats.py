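"""Trajectory and learning summaries: learning curves, regimes, switching.

Learning curves track, over training time, the ensemble-mean response
probabilities for the behaviourally meaningful percept/action pairs —
keeping direction when the net flow agrees (s = +2, a = +1), turning around
when it opposes (s = −2, a = −1), and turning at zero net flow (s = 0,
a = −1), which stays at 1/2 absent asymmetric rewards.

Regime summaries operationalise the qualitative dynamical regimes of the
alignment parameter: disordered (z fluctuates around 0), intermediate
(global alignment with stochastic direction switches) and ordered (stable
long-term alignment).  Direction switches are counted with a two-threshold
hysteresis rule so that noise crossings near z = 0 are not counted: a
switch is registered only when z moves from ≤ −θ to ≥ +θ or vice versa
(default θ = 0.3).  The regime thresholds are declared, configurable
conventions; the underlying distinction is qualitative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TRACKED_PAIRS",
    "LearningCurve",
    "RegimeSummary",
    "learning_curves",
    "switching_statistics",
    "regime_classify",
]

#: (percept, action) pairs tracked by default in learning curves.
TRACKED_PAIRS = ((2, 1), (-2, -1), (0, -1))

#: LearningCurve is a tidy DataFrame with columns t, s, a, p_mean, p_sd.
LearningCurve = pd.DataFrame


@dataclass
class RegimeSummary:
    """Alignment statistics of one trajectory window."""

    mean_abs_z: float
    n_switches: int
    mean_dwell: float | None  # mean sweeps between consecutive switches
    switch_rate: float  # switches per sweep
    label: str  # "disordered" | "intermediate" | "ordered"

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_abs_z <= 1.0 + 1e-12) or self.n_switches < 0:
            raise ValueError("invalid regime summary")


def learning_curves(snapshots, pairs=TRACKED_PAIRS) -> LearningCurve:
    """Ensemble-mean response probabilities over training time.

    ``snapshots`` is a sequence of ``(t, memories)`` pairs where memories has
    shape ``(..., 5, 2)`` (any leading axes — agents, or runs × agents — are
    pooled).  For each snapshot the per-agent probabilities P(a|s) are
    computed by row normalisation and then averaged; ``p_sd`` is the
    dispersion across agents.
    """
    snapshots = list(snapshots)
    if len(snapshots) < 2:
        raise ValueError("need memory snapshots at >= 2 times")
    rows = []
    for t, mem in snapshots:
        mem = np.asarray(mem, dtype=float).reshape(-1, 5, 2)
        probs = mem / mem.sum(axis=2, keepdims=True)
        for s, a in pairs:
            p = probs[:, s + 2, (a + 1) // 2]
            rows.append((t, s, a, p.mean(), p.std()))
    return pd.DataFrame(rows, columns=["t", "s", "a", "p_mean", "p_sd"])


def switching_statistics(
    z_series,
    theta: float = 0.3,
    *,
    disordered_max: float = 0.3,
    ordered_min: float = 0.6,
    ordered_max_switch_rate: float = 1.0 / 1000.0,
) -> RegimeSummary:
    """Direction-switch count and regime label for an alignment series.

    A switch is counted when z crosses from ≤ −θ to ≥ +θ or vice versa
    (hysteresis: the series must fully traverse the ±θ band).  Dwell times
    are the gaps between consecutive switches.
    """
    z = np.asarray(getattr(z_series, "z", z_series), dtype=float)
    if z.size == 0:
        raise ValueError("empty alignment series")
    if not (0.0 < theta < 1.0):
        raise ValueError("threshold theta must lie in (0, 1)")
    armed = 0  # last fully-entered side: −1, +1, or 0 before first entry
    switch_times = []
    for t, value in enumerate(z):
        side = 1 if value >= theta else (-1 if value <= -theta else 0)
        if side and side != armed:
            if armed:  # crossing from the opposite side: a genuine switch
                switch_times.append(t)
            armed = side
    dwell = np.diff(switch_times)
    mean_dwell = float(dwell.mean()) if dwell.size else None
    n_switches = len(switch_times)
    duration = max(len(z) - 1, 1)
    summary = RegimeSummary(
        mean_abs_z=float(np.abs(z).mean()),
        n_switches=n_switches,
        mean_dwell=mean_dwell,
        switch_rate=n_switches / duration,
        label="",
    )
    summary.label = regime_classify(
        summary,
        disordered_max=disordered_max,
        ordered_min=ordered_min,
        ordered_max_switch_rate=ordered_max_switch_rate,
    )
    return summary


def regime_classify(
    summary: RegimeSummary,
    *,
    disordered_max: float = 0.3,
    ordered_min: float = 0.6,
    ordered_max_switch_rate: float = 1.0 / 1000.0,
) -> str:
    """Label a summary: disordered if mean |z| < ``disordered_max``; ordered
    if mean |z| ≥ ``ordered_min`` and the switch rate stays below
    ``ordered_max_switch_rate``; intermediate otherwise."""
    if summary.mean_abs_z < disordered_max:
        return "disordered"
    if summary.mean_abs_z >= ordered_min and summary.switch_rate < ordered_max_switch_rate:
        return "ordered"
    return "intermediate"
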