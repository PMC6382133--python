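"""Simulation orchestration: configuration, runs, trajectory I/O and the CLI.

A :class:`SimulationConfig` plus its seed fully determine every output byte
of a run.  Named presets cover the standard study conditions (world W = 80,
sensory range r = 5, hence B = 8 neighbourhoods; populations N ∈ {10, 40, 70};
decisiveness d ∈ {1, 5, 30} for fixed-disposition agents; forgetting
γ ∈ {0, 0.002} for learning agents).

The CLI (``locustswarm`` console script / ``python -m locustswarm``) is a
thin layer over the library: subcommands ``simulate``, ``kernel``, ``fpe``,
``learncurves`` and ``regimes`` write the CSV artefacts described in their
``--help`` text.
"""

from __future__ import annotations

import argparse
import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arena import SwarmState, WorldConfig, _sweep_batch, init_swarm
from .ps_agent import PERCEPTS, AgentParams, make_fixed_disposition

log = logging.getLogger("locustswarm")

__all__ = [
    "ConfigError",
    "SchemaError",
    "SimulationConfig",
    "TrajectoryRecord",
    "PRESETS",
    "preset",
    "load_config",
    "run_simulation",
    "run_ensemble",
    "write_trajectory",
    "read_trajectory",
    "main",
]


class ConfigError(ValueError):
    """Invalid or inconsistent simulation configuration."""


class SchemaError(ValueError):
    """A CSV artefact does not match its documented column schema."""


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one run.

    record
        ``"z"`` — alignment series only; ``"events"`` — additionally a
        long-format per-turn log of (agent, percept, action, reward).
    snapshot_every
        If set, store a copy of all memories every that-many sweeps
        (plus the initial and final state).
    move
        ``"per_sweep"`` (default): all agents advance one block after the
        N-th turn; ``"per_turn"``: each agent steps right after its turn.
    """

    W: int = 80
    r: int = 5
    N: int = 40
    mode: str = "fixed"
    d: float | None = None
    gamma: float | None = None
    inertia: float = 0.0
    steps: int = 1000
    seed: int = 0
    record: str = "z"
    snapshot_every: int | None = None
    move: str = "per_sweep"
    reward_ties: bool = False

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ConfigError("steps must be >= 1")
        if self.mode not in ("fixed", "learning"):
            raise ConfigError(f"mode must be 'fixed' or 'learning', got {self.mode!r}")
        if self.record not in ("z", "events"):
            raise ConfigError(f"record must be 'z' or 'events', got {self.record!r}")
        if self.move not in ("per_sweep", "per_turn"):
            raise ConfigError(f"move must be 'per_sweep' or 'per_turn', got {self.move!r}")
        if self.mode == "fixed":
            if self.gamma is not None:
                raise ConfigError("mode='fixed' is incompatible with a forgetting gamma")
            if self.d is None:
                raise ConfigError("mode='fixed' requires a decisiveness d")
        else:
            if self.gamma is None:
                raise ConfigError("mode='learning' requires a forgetting gamma")
            if self.d is not None:
                raise ConfigError("mode='learning' is incompatible with a decisiveness d")
        # delegate range checks
        self.world()
        self.agent_params()

    def world(self) -> WorldConfig:
        return WorldConfig(self.W, self.r, self.N)

    def agent_params(self) -> AgentParams:
        return AgentParams(self.mode, self.d, self.gamma, self.inertia)


#: Named study conditions (W = 80, r = 5 throughout, i.e. B = 8).
PRESETS: dict[str, dict] = {
    "fig2a": dict(N=10, mode="fixed", d=30.0),
    "fig2b": dict(N=40, mode="fixed", d=30.0),
    "fig2c": dict(N=70, mode="fixed", d=30.0),
    "fig4a": dict(N=10, mode="learning", gamma=0.002),
    "fig4b": dict(N=40, mode="learning", gamma=0.002),
    "fig4c": dict(N=70, mode="learning", gamma=0.002),
    "fig7": dict(N=10, mode="learning", gamma=0.0),
}


def preset(name: str, **overrides) -> SimulationConfig:
    """A :class:`SimulationConfig` for a named study condition."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(W=80, r=5, **PRESETS[name])
    kw.update(overrides)
    return SimulationConfig(**kw)


def load_config(path, **overrides) -> SimulationConfig:
    """Read a flat YAML/JSON mapping of SimulationConfig fields."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a flat mapping")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    data.update(overrides)
    return SimulationConfig(**data)


@dataclass
class TrajectoryRecord:
    """Time series of the alignment parameter plus optional logs.

    z has length steps + 1; index 0 is the initial random state and each
    later entry is recorded after a completed sweep.  ``events`` is a
    long-format DataFrame (t, agent_id, percept, action, reward); snapshots
    are ``(t, memories (N, 5, 2))`` pairs.
    """

    z: np.ndarray
    config: SimulationConfig | None = None
    events: pd.DataFrame | None = None
    snapshots: list[tuple[int, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)


def _run_batch(config: SimulationConfig, n_runs: int):
    """Advance ``n_runs`` replicate swarms from one seeded stream.

    Returns (z (n_runs, steps+1), snapshots [(t, (n_runs, N, 5, 2))],
    events list or None, final SwarmState arrays).
    """
    rng = np.random.default_rng(config.seed)
    cfg = config.world()
    params = config.agent_params()
    proto = init_swarm(cfg, params, rng)  # consumes the init draws for run 0
    positions = np.empty((n_runs, cfg.N), dtype=np.int64)
    headings = np.empty((n_runs, cfg.N), dtype=np.int64)
    positions[0] = proto.positions
    headings[0] = proto.headings
    for k in range(1, n_runs):
        positions[k] = rng.integers(0, cfg.W, size=cfg.N)
        headings[k] = rng.integers(0, 2, size=cfg.N) * 2 - 1
    memories = np.broadcast_to(proto.memories, (n_runs, cfg.N, 5, 2)).copy()

    learning = config.mode == "learning"
    gamma = config.gamma if learning else 0.0
    p_continue = None
    mem_arg = memories
    if not learning:
        # homogeneous frozen policy: precompute P(continue | s)
        p_continue = proto.memories[0, :, 1] / proto.memories[0].sum(axis=1)
        mem_arg = None

    steps = config.steps
    z = np.empty((n_runs, steps + 1))
    z[:, 0] = headings.mean(axis=1)
    snaps: list[tuple[int, np.ndarray]] = []
    k_snap = config.snapshot_every
    if k_snap:
        snaps.append((0, memories.copy()))
    raw_events: list | None = [] if config.record == "events" else None
    all_events: list = []
    for t in range(1, steps + 1):
        _sweep_batch(
            positions,
            headings,
            cfg,
            rng,
            memories=mem_arg,
            p_continue=p_continue,
            learning=learning,
            gamma=gamma or 0.0,
            move=config.move,
            reward_ties=config.reward_ties,
            events=raw_events,
        )
        z[:, t] = headings.mean(axis=1)
        if k_snap and (t % k_snap == 0 or t == steps):
            snaps.append((t, memories.copy()))
        if raw_events is not None:
            all_events.extend((t, i, s, a, rw) for i, s, a, rw in raw_events)
            raw_events.clear()
    final = SwarmState(positions[0], headings[0], memories[0], params, t=steps)
    return z, snaps, (all_events if config.record == "events" else None), final


def run_simulation(config: SimulationConfig) -> TrajectoryRecord:
    """Run one seeded simulation and record the alignment trajectory.

    Re-running with the same config is bit-identical.
    """
    log.info("run_simulation v%s config=%s", __version__, config)
    zs, snaps, events, _ = _run_batch(config, n_runs=1)
    ev_frame = None
    if events is not None:
        ev_frame = pd.DataFrame(
            [(t, i, int(s[0]), int(a[0]), int(rw[0])) for t, i, s, a, rw in events],
            columns=["t", "agent_id", "percept", "action", "reward"],
        )
    return TrajectoryRecord(
        z=zs[0],
        config=config,
        events=ev_frame,
        snapshots=[(t, m[0]) for t, m in snaps],
    )


def run_ensemble(config: SimulationConfig, n_runs: int) -> list[TrajectoryRecord]:
    """``n_runs`` independent replicates driven by one seeded stream.

    Replicates are advanced in lock-step by the vectorised core; they are
    statistically independent realisations of the same study condition.
    Event logging is only available through :func:`run_simulation`.
    """
    if config.record == "events":
        raise ConfigError("event logging is not supported for ensemble runs")
    zs, snaps, _, _ = _run_batch(config, n_runs)
    return [
        TrajectoryRecord(
            z=zs[k],
            config=config,
            snapshots=[(t, m[k]) for t, m in snaps],
        )
        for k in range(n_runs)
    ]


# ---------------------------------------------------------------------------
# trajectory I/O
#
# <path>            t,z                       (always)
# <path>.events.csv t,agent_id,percept,action,reward   (if events recorded)
# <path>.memory.csv t,agent_id,s,a,h          (if snapshots recorded)

_Z_COLS = ["t", "z"]
_EVENT_COLS = ["t", "agent_id", "percept", "action", "reward"]
_MEMORY_COLS = ["t", "agent_id", "s", "a", "h"]


def _sidecars(path) -> tuple[Path, Path]:
    p = Path(path)
    return p.with_name(p.name + ".events.csv"), p.with_name(p.name + ".memory.csv")


def write_trajectory(record: TrajectoryRecord, path) -> None:
    """Write a record as CSV (schema ``t,z`` plus optional sidecar tables)."""
    frame = pd.DataFrame({"t": np.arange(len(record.z)), "z": record.z})
    frame.to_csv(path, index=False)
    events_path, memory_path = _sidecars(path)
    if record.events is not None:
        record.events.to_csv(events_path, index=False)
    if record.snapshots:
        rows = []
        for t, mem in record.snapshots:
            for i in range(mem.shape[0]):
                for si, s in enumerate(PERCEPTS):
                    for ai, a in enumerate((-1, 1)):
                        rows.append((t, i, s, a, mem[i, si, ai]))
        pd.DataFrame(rows, columns=_MEMORY_COLS).to_csv(memory_path, index=False)


def read_trajectory(path) -> TrajectoryRecord:
    """Read a record written by :func:`write_trajectory` (lossless for z/logs)."""
    frame = pd.read_csv(path)
    if list(frame.columns) != _Z_COLS:
        raise SchemaError(f"expected columns {_Z_COLS}, found {list(frame.columns)}")
    events_path, memory_path = _sidecars(path)
    events = None
    if events_path.exists():
        events = pd.read_csv(events_path)
        if list(events.columns) != _EVENT_COLS:
            raise SchemaError(f"expected columns {_EVENT_COLS} in {events_path}")
    snapshots: list[tuple[int, np.ndarray]] = []
    if memory_path.exists():
        mem_frame = pd.read_csv(memory_path)
        if list(mem_frame.columns) != _MEMORY_COLS:
            raise SchemaError(f"expected columns {_MEMORY_COLS} in {memory_path}")
        for t, block in mem_frame.groupby("t"):
            n_agents = block["agent_id"].nunique()
            mem = np.empty((n_agents, 5, 2))
            for row in block.itertuples(index=False):
                mem[int(row.agent_id), int(row.s) + 2, (int(row.a) + 1) // 2] = row.h
            snapshots.append((int(t), mem))
    return TrajectoryRecord(z=frame["z"].to_numpy(), events=events, snapshots=snapshots)


# ---------------------------------------------------------------------------
# command-line interface


def _add_world_flags(p: argparse.ArgumentParser) -> None:
    p.add_argument("-W", type=int, default=80, help="world size in blocks")
    p.add_argument("-r", type=int, default=5, help="sensory range in blocks")
    p.add_argument("-N", type=int, default=40, help="population size")


def _build_parser() -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(
        prog="locustswarm",
        description="Learning-agent model of density-dependent alignment on a ring.",
    )
    parser.add_argument("--version", action="version", version=__version__)
    sub = parser.add_subparsers(dest="command", required=True)

    sim = sub.add_parser("simulate", help="run one simulation, write t,z CSV")
    sim.add_argument("--preset", choices=sorted(PRESETS), help="named study condition")
    sim.add_argument("--config", help="YAML/JSON config file (CLI flags override)")
    sim.add_argument("-W", type=int, default=None, help="world size in blocks")
    sim.add_argument("-r", type=int, default=None, help="sensory range in blocks")
    sim.add_argument("-N", type=int, default=None, help="population size")
    sim.add_argument("--mode", choices=["fixed", "learning"], default=None)
    sim.add_argument("-d", type=float, default=None, help="decisiveness (fixed mode)")
    sim.add_argument("--gamma", type=float, default=None, help="forgetting (learning mode)")
    sim.add_argument("--inertia", type=float, default=0.0)
    sim.add_argument("--steps", type=int, default=1000)
    sim.add_argument("--seed", type=int, default=0)
    sim.add_argument("--record", choices=["z", "events"], default="z")
    sim.add_argument("--snapshot-every", type=int, default=None)
    sim.add_argument("--move", choices=["per_sweep", "per_turn"], default="per_sweep")
    sim.add_argument("--reward-ties", action="store_true")
    sim.add_argument("--out", required=True, help="output CSV path")

    ker = sub.add_parser("kernel", help="Monte-Carlo transition kernel P(z'|z)")
    _add_world_flags(ker)
    ker.add_argument("-d", type=float, default=30.0)
    ker.add_argument("--inertia", type=float, default=0.0)
    ker.add_argument("--samples", type=int, default=10000, help="samples per grid row")
    ker.add_argument("--seed", type=int, default=0)
    ker.add_argument("--reward-ties", action="store_true")
    ker.add_argument("--out", required=True, help="long-format z,zprime,p CSV")

    fpe = sub.add_parser("fpe", help="drift F(z), diffusion D(z) and fixed points")
    fpe.add_argument("--mode", choices=["fixed"], default="fixed")
    fpe.add_argument("-d", type=float, default=30.0)
    fpe.add_argument("--inertia", type=float, default=0.0)
    fpe.add_argument("-N", type=int, default=40)
    fpe.add_argument("-B", type=float, default=None, help="neighbourhood count (with -r)")
    fpe.add_argument("-W", type=int, default=None)
    fpe.add_argument("-r", type=int, default=5)
    fpe.add_argument(
        "--method", choices=["meanfield", "kernel"], default="kernel",
        help="mean-field computation or Monte-Carlo kernel estimate",
    )
    fpe.add_argument("--samples", type=int, default=10000)
    fpe.add_argument("--seed", type=int, default=0)
    fpe.add_argument("--out", required=True, help="z,F,D,se_F,se_D,method CSV")
    fpe.add_argument("--fixed-points-out", default=None, help="z0,slope,stability CSV")

    lc = sub.add_parser("learncurves", help="ensemble learning curves P(a|s)(t)")
    _add_world_flags(lc)
    lc.add_argument("--gamma", type=float, default=0.002)
    lc.add_argument("--steps", type=int, default=5000)
    lc.add_argument("--runs", type=int, default=1)
    lc.add_argument("--snapshot-every", type=int, default=50)
    lc.add_argument("--seed", type=int, default=0)
    lc.add_argument("--out", required=True, help="t,s,a,p_mean,p_sd CSV")

    reg = sub.add_parser("regimes", help="regime labels and switching statistics")
    _add_world_flags(reg)
    reg.add_argument("--mode", choices=["fixed", "learning"], default="fixed")
    reg.add_argument("-d", type=float, default=30.0)
    reg.add_argument("--gamma", type=float, default=None)
    reg.add_argument("--steps", type=int, default=2000)
    reg.add_argument("--runs", type=int, default=1)
    reg.add_argument("--theta", type=float, default=0.3)
    reg.add_argument("--seed", type=int, default=0)
    reg.add_argument("--out", required=True, help="run_id,mean_abs_z,switches,label CSV")
    return parser


def _world_from_args(args) -> WorldConfig:
    if getattr(args, "B", None) is not None and args.W is None:
        W = int(round(2 * args.r * args.B))
    else:
        W = args.W if args.W is not None else 80
    return WorldConfig(W, args.r, args.N)


def _cmd_simulate(args) -> int:
    explicit = dict(
        W=args.W, r=args.r, N=args.N, mode=args.mode, d=args.d, gamma=args.gamma,
        inertia=args.inertia, steps=args.steps, seed=args.seed, record=args.record,
        snapshot_every=args.snapshot_every, move=args.move, reward_ties=args.reward_ties,
    )
    explicit = {k: v for k, v in explicit.items() if v is not None}
    if args.preset:
        merged = dict(W=80, r=5, **PRESETS[args.preset])
        if "mode" in explicit and explicit["mode"] != merged["mode"]:
            merged.pop("d", None)
            merged.pop("gamma", None)
        merged.update(explicit)
        config = SimulationConfig(**merged)
    elif args.config:
        config = load_config(args.config, **explicit)
    else:
        explicit.setdefault("mode", "fixed")
        if explicit["mode"] == "fixed":
            explicit.setdefault("d", 30.0)
        config = SimulationConfig(**explicit)
    record = run_simulation(config)
    write_trajectory(record, args.out)
    log.info("wrote %s (%d sweeps, seed %d)", args.out, config.steps, config.seed)
    return 0


def _cmd_kernel(args) -> int:
    from .fpe import estimate_transition_kernel

    cfg = WorldConfig(args.W, args.r, args.N)
    policy = make_fixed_disposition(args.d, args.inertia)
    rng = np.random.default_rng(args.seed)
    kernel = estimate_transition_kernel(
        cfg, policy, args.samples, rng, reward_ties=args.reward_ties
    )
    kernel.to_frame().to_csv(args.out, index=False)
    return 0


def _cmd_fpe(args) -> int:
    from .fpe import (
        estimate_transition_kernel,
        find_fixed_points,
        km_from_kernel,
        meanfield_drift_diffusion,
    )

    policy = make_fixed_disposition(args.d, args.inertia)
    if args.method == "meanfield":
        B = args.B if args.B is not None else _world_from_args(args).B
        curves = meanfield_drift_diffusion(args.N, B, policy)
    else:
        cfg = _world_from_args(args)
        rng = np.random.default_rng(args.seed)
        kernel = estimate_transition_kernel(cfg, policy, args.samples, rng)
        curves = km_from_kernel(kernel)
    curves.to_frame().to_csv(args.out, index=False)
    if args.fixed_points_out:
        find_fixed_points(curves).to_frame().to_csv(args.fixed_points_out, index=False)
    return 0


def _cmd_learncurves(args) -> int:
    from .collective_stats import learning_curves

    config = SimulationConfig(
        W=args.W, r=args.r, N=args.N, mode="learning", gamma=args.gamma,
        steps=args.steps, seed=args.seed, snapshot_every=args.snapshot_every,
    )
    records = run_ensemble(config, args.runs)
    times = [t for t, _ in records[0].snapshots]
    stacked = [
        (t, np.stack([rec.snapshots[j][1] for rec in records]))
        for j, t in enumerate(times)
    ]
    learning_curves(stacked).to_csv(args.out, index=False)
    return 0


def _cmd_regimes(args) -> int:
    from .collective_stats import switching_statistics

    config = SimulationConfig(
        W=args.W, r=args.r, N=args.N, mode=args.mode,
        d=args.d if args.mode == "fixed" else None,
        gamma=args.gamma if args.mode == "learning" else None,
        steps=args.steps, seed=args.seed,
    )
    records = run_ensemble(config, args.runs)
    rows = []
    for k, rec in enumerate(records):
        summary = switching_statistics(rec.z, args.theta)
        rows.append((k, summary.mean_abs_z, summary.n_switches, summary.label))
    pd.DataFrame(rows, columns=["run_id", "mean_abs_z", "switches", "label"]).to_csv(
        args.out, index=False
    )
    return 0


_COMMANDS = {
    "simulate": _cmd_simulate,
    "kernel": _cmd_kernel,
    "fpe": _cmd_fpe,
    "learncurves": _cmd_learncurves,
    "regimes": _cmd_regimes,
}


def main(argv: list[str] | None = None) -> int:
    """CLI entry point; returns a process exit code."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    parser = _build_parser()
    try:
        args = parser.parse_args(argv)
    except SystemExit as exc:  # argparse exits on --help / bad flags
        return int(exc.code or 0)
    try:
        return _COMMANDS[args.command](args)
    except (ConfigError, ValueError, OSError) as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 2


if __name__ == "__main__":  # pragma: no cover
    raise SystemExit(main())
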