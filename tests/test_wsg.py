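"""Wolf-Sheep-Grass model: initialization, tick dynamics, summarization,
and uniform-random microstate synthesis."""

import numpy as np
import pytest

from abmda.macrostate import Macrostate
from abmda.wsg import (
    AgentSet,
    WSGMicrostate,
    WSGParams,
    init_wsg,
    step_wsg,
    summarize_wsg,
    synthesize_wsg,
    wsg_schema,
)


def _single_sheep_state(world=8, energy=5.0, pos=(3.5, 3.5), all_green=True):
    grass = np.full((world, world), all_green)
    regrowth = np.zeros((world, world), dtype=np.int64)
    sheep = AgentSet(np.array([pos]), np.array([0.0]), np.array([energy]))
    return WSGMicrostate(AgentSet.empty(), sheep, grass, regrowth)


class TestInit:
    def test_full_grass_density_means_no_regrowth_counters(self):
        p = WSGParams(world_size=16, init_grass_density=1.0, init_wolves=2, init_sheep=2)
        s = init_wsg(p, 0)
        assert s.grass.all()
        assert not s.regrowth.any()

    def test_zero_wolves_summarizes_to_zero(self):
        p = WSGParams(world_size=16, init_wolves=0, init_sheep=5)
        assert summarize_wsg(init_wsg(p, 0))["wolves"] == 0

    def test_same_seed_gives_identical_state(self, small_wsg_params):
        a = init_wsg(small_wsg_params, 7)
        b = init_wsg(small_wsg_params, 7)
        np.testing.assert_array_equal(a.grass, b.grass)
        np.testing.assert_array_equal(a.wolves.pos, b.wolves.pos)
        np.testing.assert_array_equal(a.sheep.energy, b.sheep.energy)

    def test_invalid_world_size_rejected(self):
        with pytest.raises(ValueError):
            WSGParams(world_size=0)

    def test_initial_state_satisfies_invariants(self, small_wsg_state, small_wsg_params):
        small_wsg_state.validate(small_wsg_params)


class TestStep:
    def test_empty_world_with_full_grass_is_fixed(self):
        p = WSGParams(world_size=8, init_wolves=0, init_sheep=0, init_grass_density=1.0)
        s = init_wsg(p, 0)
        s2 = step_wsg(s, p, np.random.default_rng(0))
        np.testing.assert_array_equal(s2.grass, s.grass)
        assert len(s2.wolves) == 0 and len(s2.sheep) == 0

    def test_grazing_sheep_energy_and_patch_hand_trace(self):
        # stationary sheep (step_length 0) on green grass, reproduction off:
        # energy e - move_cost + sheep_gain; patch goes brown with a full
        # regrowth counter
        p = WSGParams(
            world_size=8, sheep_reproduce_prob=0.0, sheep_gain=4.0, move_cost=1.0,
            grass_regrowth_time=30, step_length=0.0, init_wolves=0, init_sheep=0,
        )
        s = _single_sheep_state(energy=5.0)
        s2 = step_wsg(s, p, np.random.default_rng(0))
        assert s2.sheep.energy[0] == pytest.approx(5.0 - 1.0 + 4.0)
        assert not s2.grass[3, 3]
        assert s2.regrowth[3, 3] == 30

    def test_starving_agent_removed_same_tick(self):
        # energy <= move_cost and nothing to eat -> dies this tick
        p = WSGParams(
            world_size=8, sheep_reproduce_prob=0.0, move_cost=1.0,
            step_length=0.0, init_wolves=0, init_sheep=0,
        )
        s = _single_sheep_state(energy=1.0, all_green=False)
        s.regrowth[:] = 5
        s2 = step_wsg(s, p, np.random.default_rng(0))
        assert len(s2.sheep) == 0

    def test_reproduction_conserves_energy_exactly(self):
        p = WSGParams(
            world_size=8, sheep_reproduce_prob=1.0, move_cost=0.0,
            step_length=0.0, init_wolves=0, init_sheep=0,
        )
        s = _single_sheep_state(energy=7.0, all_green=False)
        s.regrowth[:] = 5
        s2 = step_wsg(s, p, np.random.default_rng(0))
        assert len(s2.sheep) == 2
        assert s2.sheep.energy.sum() == pytest.approx(7.0)

    def test_wolf_eats_exactly_one_sheep(self):
        p = WSGParams(
            world_size=8, wolf_reproduce_prob=0.0, sheep_reproduce_prob=0.0,
            wolf_gain=20.0, move_cost=1.0, step_length=0.0,
            init_wolves=0, init_sheep=0,
        )
        grass = np.zeros((8, 8), dtype=bool)
        regrowth = np.full((8, 8), 5, dtype=np.int64)
        wolves = AgentSet(np.array([[3.5, 3.5]]), np.zeros(1), np.array([10.0]))
        sheep = AgentSet(
            np.array([[3.2, 3.7], [3.8, 3.1]]), np.zeros(2), np.array([9.0, 9.0])
        )
        s = WSGMicrostate(wolves, sheep, grass, regrowth)
        s2 = step_wsg(s, p, np.random.default_rng(0))
        assert len(s2.sheep) == 1
        assert s2.wolves.energy[0] == pytest.approx(10.0 - 1.0 + 20.0)

    def test_grass_regrows_fully_within_regrowth_time(self):
        p = WSGParams(
            world_size=8, init_wolves=0, init_sheep=0,
            init_grass_density=0.3, grass_regrowth_time=10,
        )
        s = init_wsg(p, 3)
        rng = np.random.default_rng(0)
        counts = [int(s.grass.sum())]
        for _ in range(p.grass_regrowth_time):
            s = step_wsg(s, p, rng)
            counts.append(int(s.grass.sum()))
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] == p.world_size**2

    def test_identical_seed_gives_identical_trajectory(self, small_wsg_params):
        s0 = init_wsg(small_wsg_params, 5)
        out = []
        for _ in range(2):
            s = s0.copy()
            rng = np.random.default_rng(99)
            for _ in range(20):
                s = step_wsg(s, small_wsg_params, rng)
            out.append(summarize_wsg(s).values)
        np.testing.assert_array_equal(out[0], out[1])


class TestSummarize:
    def test_counts_constructed_state(self):
        grass = np.zeros((8, 8), dtype=bool)
        grass.reshape(-1)[:7] = True
        regrowth = np.where(grass, 0, 3).astype(np.int64)
        wolves = AgentSet(np.full((3, 2), 1.5), np.zeros(3), np.ones(3))
        sheep = AgentSet(np.full((5, 2), 2.5), np.zeros(5), np.ones(5))
        m = summarize_wsg(WSGMicrostate(wolves, sheep, grass, regrowth))
        np.testing.assert_array_equal(m.values, [3, 5, 7])

    def test_empty_brown_world_is_zero_vector(self):
        grass = np.zeros((4, 4), dtype=bool)
        m = summarize_wsg(
            WSGMicrostate(
                AgentSet.empty(), AgentSet.empty(), grass,
                np.full((4, 4), 2, dtype=np.int64),
            )
        )
        np.testing.assert_array_equal(m.values, [0, 0, 0])

    def test_invariant_under_agent_permutation(self, small_wsg_state, rng):
        perm = rng.permutation(len(small_wsg_state.sheep))
        shuffled = WSGMicrostate(
            small_wsg_state.wolves,
            small_wsg_state.sheep.subset(perm),
            small_wsg_state.grass,
            small_wsg_state.regrowth,
        )
        assert summarize_wsg(shuffled) == summarize_wsg(small_wsg_state)


class TestSynthesize:
    def test_identity_target_is_fixed_point(self, small_wsg_state, small_wsg_params, rng):
        target = summarize_wsg(small_wsg_state)
        out = synthesize_wsg(target, small_wsg_state, small_wsg_params, rng)
        np.testing.assert_array_equal(out.sheep.pos, small_wsg_state.sheep.pos)
        np.testing.assert_array_equal(out.grass, small_wsg_state.grass)

    @pytest.mark.parametrize("target_counts", [(0, 0, 0), (3, 40, 100), (20, 5, 256)])
    def test_round_trip_reaches_target_exactly(
        self, small_wsg_state, small_wsg_params, rng, target_counts
    ):
        target = Macrostate(wsg_schema(16), target_counts)
        out = synthesize_wsg(target, small_wsg_state, small_wsg_params, rng)
        np.testing.assert_array_equal(summarize_wsg(out).values, target_counts)
        out.validate(small_wsg_params)

    def test_surplus_removal_keeps_a_subset(self, small_wsg_state, small_wsg_params, rng):
        n = len(small_wsg_state.sheep)
        target = Macrostate(
            wsg_schema(16),
            [len(small_wsg_state.wolves), n - 3, int(small_wsg_state.grass.sum())],
        )
        out = synthesize_wsg(target, small_wsg_state, small_wsg_params, rng)
        assert len(out.sheep) == n - 3
        original = {tuple(p) for p in small_wsg_state.sheep.pos}
        assert all(tuple(p) in original for p in out.sheep.pos)

    def test_infeasible_grass_target_rejected(self, small_wsg_state, small_wsg_params, rng):
        target = Macrostate(wsg_schema(16), [0, 0, 16 * 16 + 1])
        with pytest.raises(ValueError):
            synthesize_wsg(target, small_wsg_state, small_wsg_params, rng)
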