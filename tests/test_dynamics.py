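import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latticepd import (
    Params,
    Population,
    Strategy,
    elementary_update,
    fermi_probability,
    mc_step,
    run,
)

from conftest import random_population

CN, DN, CP, DP = Strategy.CN, Strategy.DN, Strategy.CP, Strategy.DP


class TestFermi:
    def test_equal_payoffs_give_half(self):
        assert fermi_probability(3.7, 3.7, 10.0) == 0.5

    def test_zero_imitation_strength_is_random(self):
        for pi, pj in [(0.0, 25.0), (-8.0, 8.0), (100.0, -100.0)]:
            assert fermi_probability(pi, pj, 0.0) == 0.5

    def test_closed_form_value(self):
        # payoff gap -0.5 at kappa = 10: 1 / (1 + e^-5)
        assert fermi_probability(1.0, 1.5, 10.0) == pytest.approx(
            1.0 / (1.0 + math.exp(-5.0)), abs=1e-12
        )

    def test_large_gaps_saturate_without_overflow(self):
        assert fermi_probability(-1e6, 1e6, 10.0) == 1.0
        assert fermi_probability(1e6, -1e6, 10.0) == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        pi=st.floats(-30, 30),
        gap=st.floats(0.001, 30),
        kappa=st.floats(0, 50),
    )
    def test_monotone_in_payoff_advantage(self, pi, gap, kappa):
        w_better = fermi_probability(pi, pi + gap, kappa)
        w_worse = fermi_probability(pi, pi - gap, kappa)
        assert 0.0 <= w_worse <= 0.5 <= w_better <= 1.0


class TestElementaryUpdate:
    def test_mutates_only_focal_site(self):
        p = Params(r=0.2, beta=0.2, gamma=0.05, mode="direct", L=6,
                   steps_total=1, steps_average=1)
        pop = random_population(6, seed=1)
        before = pop.grid.copy()
        rec = elementary_update(pop, p, np.random.default_rng(0))
        diff = np.flatnonzero(pop.grid.ravel() != before.ravel())
        assert set(diff) <= {rec.focal}
        assert 0.0 <= rec.prob <= 1.0
        assert rec.model_neighbor in set(pop.first_order[rec.focal])

    def test_identical_seed_gives_identical_records(self):
        p = Params(r=0.2, beta=0.1, gamma=0.02, mode="indirect", L=6,
                   steps_total=1, steps_average=1)
        runs = []
        for _ in range(2):
            pop = random_population(6, seed=3)
            rng = np.random.default_rng(42)
            runs.append([elementary_update(pop, p, rng) for _ in range(30)])
        assert runs[0] == runs[1]

    def test_shared_strategy_leaves_configuration_unchanged(self):
        grid = np.full((6, 6), int(CP), dtype=np.int8)
        pop = Population.from_grid(grid)
        p = Params(r=0.2, beta=0.3, gamma=0.3, mode="direct", L=6,
                   steps_total=1, steps_average=1)
        for s in range(20):
            elementary_update(pop, p, np.random.default_rng(s))
        assert np.all(pop.grid == int(CP))

    def test_strong_imitation_copies_better_neighbor(self):
        # lone defector among cooperators earns 8(1+r) > 8; with huge kappa
        # a cooperator focal bordering it must imitate (prob -> 1)
        grid = np.full((6, 6), int(CN), dtype=np.int8)
        grid[2, 2] = int(DN)
        pop = Population.from_grid(grid)
        p = Params(r=0.2, mode="none", L=6, kappa=1e6, steps_total=1, steps_average=1)

        class ForcedRng:
            def __init__(self):
                self.calls = 0

            def integers(self, n):
                # focal (2,1), then its neighbor index pointing at (2,2)
                if self.calls == 0:
                    self.calls += 1
                    return 2 * 6 + 1
                return list(pop.first_order[2 * 6 + 1]).index(2 * 6 + 2)

            def random(self):
                return 0.999999

        rec = elementary_update(pop, p, ForcedRng())
        assert rec.prob > 0.999999 and rec.imitated
        assert pop.grid[2, 1] == int(DN)


class TestMcStepAndRun:
    def test_step_performs_n_updates(self):
        p = Params(r=0.2, L=5, steps_total=1, steps_average=1)
        pop = random_population(5, seed=0)
        records = mc_step(pop, p, np.random.default_rng(1))
        assert len(records) == 25

    @pytest.mark.parametrize("engine", ["python", "numba"])
    def test_monomorphic_population_is_absorbing(self, engine):
        p = Params(r=0.2, beta=0.2, gamma=0.1, mode="direct", L=6,
                   steps_total=5, steps_average=2, seed=9)
        pop = Population.from_grid(np.full((6, 6), int(DP), dtype=np.int8))
        traj = run(p, init=pop, engine=engine)
        assert np.all(traj.final.grid == int(DP))
        assert traj.absorbed_at == 1
        assert np.all(traj.fractions[:, DP] == 1.0)

    def test_fractions_sum_to_one_every_step(self):
        p = Params(r=0.2, beta=0.2, gamma=0.03, mode="indirect", L=10,
                   steps_total=50, steps_average=10, seed=2)
        traj = run(p)
        assert np.allclose(traj.fractions.sum(axis=1), 1.0)

    def test_equal_seeds_give_identical_trajectories(self):
        p = Params(r=0.2, beta=0.2, gamma=0.03, mode="indirect", L=10,
                   steps_total=30, steps_average=10, seed=17)
        a, b = run(p), run(p)
        assert np.array_equal(a.fractions, b.fractions)
        assert np.array_equal(a.final.grid, b.final.grid)

    def test_zero_steps_returns_initial_fractions_only(self):
        p = Params(r=0.2, L=8, steps_total=0, steps_average=0, seed=1)
        traj = run(p)
        assert traj.fractions.shape == (1, 4)

    def test_cooperator_only_population_cannot_spawn_defectors(self):
        # CN + CP mix with beta = gamma = 0: labels drift neutrally but the
        # cooperation level stays exactly 1 (no defector to imitate)
        p = Params(r=0.2, beta=0.0, gamma=0.0, mode="none", L=10,
                   steps_total=100, steps_average=20, seed=4)
        rng = np.random.default_rng(4)
        grid = rng.choice([int(CN), int(CP)], size=(10, 10)).astype(np.int8)
        traj = run(p, init=Population.from_grid(grid))
        assert np.all(traj.cooperation == 1.0)

    def test_snapshots_recorded_at_requested_steps(self):
        p = Params(r=0.2, beta=0.2, gamma=0.03, mode="direct", L=8,
                   steps_total=10, steps_average=5, seed=3)
        traj = run(p, snapshot_steps=(0, 5, 10), early_absorb=False)
        assert set(traj.snapshots) == {0, 5, 10}

    def test_python_and_numba_agree_on_deterministic_fixation(self):
        # strong imitation from a state where CP strictly dominates:
        # an all-CP lattice with one DN, large beta -> DN payoff far below
        # any neighbor, so the defector is erased under either engine
        p = Params(r=0.05, beta=5.0, gamma=0.001, mode="direct", L=6,
                   kappa=50.0, steps_total=30, steps_average=5, seed=21)
        grid = np.full((6, 6), int(CP), dtype=np.int8)
        grid[3, 3] = int(DN)
        for engine in ("python", "numba"):
            traj = run(p, init=Population.from_grid(grid), engine=engine)
            assert np.all(traj.final.grid == int(CP)), engine

    def test_trailing_mean_uses_averaging_window(self):
        p = Params(r=0.2, L=8, steps_total=10, steps_average=4, seed=5)
        traj = run(p, early_absorb=False)
        assert np.allclose(traj.trailing_mean, traj.fractions[-4:].mean(axis=0))
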