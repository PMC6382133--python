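import numpy as np
import pytest

from locustswarm import SimulationConfig, run_ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def learning_runs_n40():
    """Small ensemble of N=40, γ=0.002 learning runs with memory snapshots."""
    config = SimulationConfig(
        W=80, r=5, N=40, mode="learning", gamma=0.002,
        steps=1500, seed=2024, snapshot_every=50,
    )
    return run_ensemble(config, 4)


def stack_snapshots(records):
    """Merge per-run snapshots into (t, (runs, N, 5, 2)) pairs."""
    times = [t for t, _ in records[0].snapshots]
    return [
        (t, np.stack([rec.snapshots[j][1] for rec in records]))
        for j, t in enumerate(times)
    ]
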