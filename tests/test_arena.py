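"""Ring geometry, percepts, rewards and the asynchronous sweep."""

import numpy as np
import pytest

from locustswarm import (
    AgentParams,
    SwarmState,
    WorldConfig,
    alignment,
    compute_percept,
    compute_reward,
    init_swarm,
    make_fixed_disposition,
    ring_distance,
    sweep,
)


def make_swarm(positions, headings, params=None):
    n = len(positions)
    return SwarmState(
        np.array(positions),
        np.array(headings),
        np.ones((n, 5, 2)),
        params or AgentParams(mode="fixed", d=0.0),
    )


class TestGeometry:
    @pytest.mark.parametrize(
        "x1,x2,W,expect", [(0, 0, 80, 0), (79, 2, 80, 3), (0, 40, 80, 40)]
    )
    def test_ring_distance(self, x1, x2, W, expect):
        assert ring_distance(x1, x2, W) == expect

    def test_out_of_range_positions_rejected(self):
        with pytest.raises(ValueError):
            ring_distance(80, 0, 80)

    def test_world_config_validation(self):
        assert WorldConfig(80, 5, 70).B == 8.0
        with pytest.raises(ValueError):
            WorldConfig(10, 5, 3)  # 2r >= W
        with pytest.raises(ValueError):
            WorldConfig(80, 5, 0)


class TestPercept:
    def test_isolated_agent_sees_zero_net_flow(self):
        swarm = make_swarm([0, 40], [1, 1])
        assert compute_percept(swarm, 0, WorldConfig(80, 5, 2)) == 0

    def test_net_flow_is_clamped_at_two(self):
        # four co-moving plus one opposing neighbour: raw net flow 3 -> +2
        swarm = make_swarm([0, 1, 2, 3, 4, 5], [1, 1, 1, 1, 1, -1])
        assert compute_percept(swarm, 0, WorldConfig(80, 5, 6)) == 2

    def test_opposing_flow_counts_negative(self):
        cfg = WorldConfig(80, 5, 3)
        swarm = make_swarm([0, 2, 4], [1, -1, -1])
        assert compute_percept(swarm, 0, cfg) == -2
        swarm2 = make_swarm([0, 2, 40], [1, -1, -1])
        assert compute_percept(swarm2, 0, cfg) == -1

    def test_percept_is_translation_invariant(self, rng):
        cfg = WorldConfig(80, 5, 12)
        swarm = init_swarm(cfg, AgentParams(mode="fixed", d=1.0), rng)
        shifted = swarm.copy()
        shifted.positions = (shifted.positions + 37) % cfg.W
        for i in range(cfg.N):
            assert compute_percept(swarm, i, cfg) == compute_percept(shifted, i, cfg)

    def test_wraparound_neighbours_are_seen(self):
        swarm = make_swarm([78, 1], [1, 1])
        assert compute_percept(swarm, 0, WorldConfig(80, 5, 2)) == 1


class TestReward:
    def test_strict_majority_rewarded(self):
        swarm = make_swarm([0, 1, 2, 3], [1, 1, 1, 1])
        assert compute_reward(swarm, 0, WorldConfig(80, 5, 4)) == 1

    def test_tie_not_rewarded_by_default(self):
        swarm = make_swarm([0, 1, 2, 3, 4], [1, 1, 1, -1, -1])
        cfg = WorldConfig(80, 5, 5)
        assert compute_reward(swarm, 0, cfg) == 0
        assert compute_reward(swarm, 0, cfg, reward_ties=True) == 1

    def test_isolated_agent_never_rewarded(self):
        swarm = make_swarm([0, 40], [1, 1])
        cfg = WorldConfig(80, 5, 2)
        assert compute_reward(swarm, 0, cfg) == 0
        assert compute_reward(swarm, 0, cfg, reward_ties=True) == 0


class TestAlignment:
    def test_alignment_values(self):
        assert alignment(make_swarm([0, 1], [1, 1])) == 1.0
        assert alignment(make_swarm([0, 1], [1, -1])) == 0.0
        swarm = make_swarm(list(range(10)), [1] * 7 + [-1] * 3)
        assert alignment(swarm) == pytest.approx(0.4)


class TestSweep:
    def test_single_neutral_agent_flips_half_the_time(self):
        cfg = WorldConfig(80, 5, 1)
        rng = np.random.default_rng(0)
        swarm = init_swarm(cfg, AgentParams(mode="fixed", d=0.0), rng)
        flips = 0
        for _ in range(4000):
            nxt = sweep(swarm, cfg, rng)
            flips += nxt.headings[0] != swarm.headings[0]
            swarm = nxt
        assert abs(flips / 4000 - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_alignment_stays_on_grid_and_positions_in_range(self):
        cfg = WorldConfig(80, 5, 9)
        rng = np.random.default_rng(1)
        swarm = init_swarm(cfg, AgentParams(mode="fixed", d=5.0), rng)
        for _ in range(40):
            swarm = sweep(swarm, cfg, rng)
            z = alignment(swarm)
            assert (z * cfg.N) == pytest.approx(round(z * cfg.N))
            assert int(round(z * cfg.N)) % 2 == cfg.N % 2
            assert np.all((swarm.positions >= 0) & (swarm.positions < cfg.W))
            assert np.all(np.isin(swarm.headings, (-1, 1)))

    def test_sweep_is_deterministic_given_seed(self):
        cfg = WorldConfig(80, 5, 20)
        swarm = init_swarm(cfg, AgentParams(mode="fixed", d=30.0), np.random.default_rng(3))
        a = sweep(swarm, cfg, np.random.default_rng(42))
        b = sweep(swarm, cfg, np.random.default_rng(42))
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.headings, b.headings)
        assert a.t == b.t == swarm.t + 1

    def test_fixed_mode_memories_never_change(self):
        cfg = WorldConfig(80, 5, 15)
        rng = np.random.default_rng(4)
        swarm = init_swarm(cfg, AgentParams(mode="fixed", d=30.0), rng)
        before = swarm.memories.copy()
        for _ in range(25):
            swarm = sweep(swarm, cfg, rng)
        assert np.array_equal(swarm.memories, before)

    def test_learning_mode_updates_memories(self):
        cfg = WorldConfig(20, 2, 8)
        rng = np.random.default_rng(5)
        swarm = init_swarm(cfg, AgentParams(mode="learning", gamma=0.0), rng)
        for _ in range(20):
            swarm = sweep(swarm, cfg, rng)
        assert swarm.memories.max() > 1.0
        assert swarm.memories.min() >= 1.0

    def test_direction_flip_symmetry(self):
        """Reflecting the world (x -> -x, sigma -> -sigma) mirrors the run."""
        cfg = WorldConfig(80, 5, 16)
        swarm = init_swarm(cfg, AgentParams(mode="fixed", d=30.0), np.random.default_rng(6))
        mirror = swarm.copy()
        mirror.positions = (-mirror.positions) % cfg.W
        mirror.headings = -mirror.headings
        rng_a, rng_b = np.random.default_rng(7), np.random.default_rng(7)
        for _ in range(30):
            swarm = sweep(swarm, cfg, rng_a)
            mirror = sweep(mirror, cfg, rng_b)
            assert alignment(mirror) == pytest.approx(-alignment(swarm))

    def test_sweep_records_events(self):
        cfg = WorldConfig(80, 5, 6)
        rng = np.random.default_rng(8)
        swarm = init_swarm(cfg, AgentParams(mode="fixed", d=1.0), rng)
        events = []
        sweep(swarm, cfg, rng, events=events)
        assert len(events) == cfg.N
        for t, i, s, a, r in events:
            assert t == 1 and s in range(-2, 3) and a in (-1, 1) and r in (0, 1)


def test_init_swarm_uses_disposition_policy(rng):
    cfg = WorldConfig(80, 5, 5)
    swarm = init_swarm(cfg, AgentParams(mode="fixed", d=30.0), rng)
    assert np.array_equal(swarm.memories[2], make_fixed_disposition(30.0).h)
    learning = init_swarm(cfg, AgentParams(mode="learning", gamma=0.01), rng)
    assert np.array_equal(learning.memories, np.ones((5, 5, 2)))
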