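"""Cohort engine: transition matrices, traces, tunnels and a microsimulation oracle."""

import numpy as np
import pandas as pd
import pytest

from sbtox import (
    LifeTable,
    Technique,
    build_transition_matrix,
    run_cohort,
    run_mixed_cohort,
)
from sbtox.markov import build_dynamics, build_state_space, transition_matrix

from conftest import zero_toxicity


class TestLifeTable:
    def test_half_cycle_conversion(self):
        lt = LifeTable(np.arange(0, 101), np.full(101, 0.02))
        assert lt.half_cycle_q(50) == pytest.approx(1 - (1 - 0.02) ** 0.5, abs=1e-9)
        assert lt.half_cycle_q(50) == pytest.approx(0.010050, abs=1e-6)

    def test_validation(self):
        with pytest.raises(ValueError):
            LifeTable(np.array([0, 2]), np.array([0.1, 0.1]))
        with pytest.raises(ValueError):
            LifeTable(np.array([0, 1]), np.array([0.1, 1.5]))

    def test_csv_round_trip(self, tmp_path):
        lt = LifeTable.zero()
        lt.to_csv(tmp_path / "lt.csv")
        again = LifeTable.from_csv(tmp_path / "lt.csv")
        assert np.array_equal(lt.qx, again.qx)


class TestTransitionMatrix:
    def test_identity_under_zero_dynamics(self, ps, zero_lt):
        # with zero event and death probabilities every reachable state is
        # inert; tunnel rows still resolve out (they are unreachable, and the
        # tunnel invariant forbids self-transitions)
        T = build_transition_matrix(zero_toxicity(ps), Technique.CRT3D, 0, 70, zero_lt)
        space = build_state_space()
        reachable = [i for i in range(space.n)
                     if i not in {space.recurrent(l) for l in range(1, 5)}]
        assert np.allclose(T[reachable][:, reachable], np.eye(len(reachable)))

    def test_rows_sum_to_one_for_random_draws(self, ps, zero_lt):
        """Stochasticity over 1,000 random valid parameter draws."""
        lt = LifeTable(np.arange(0, 101), np.linspace(0.001, 0.5, 101))
        rng = np.random.default_rng(99)
        for i in range(1000):
            drawn = ps.sample(rng=rng)
            dyn = build_dynamics(drawn, Technique.CRT3D)
            cycle = int(rng.integers(0, 60))
            age = float(rng.uniform(25, 99))
            T = transition_matrix(dyn, cycle, age, lt)
            assert np.allclose(T.sum(axis=1), 1.0, atol=1e-9)
            assert T.min() >= 0.0

    def test_absorbing_states(self, ps, fx):
        space = build_state_space()
        T = build_transition_matrix(ps, Technique.IMRT, 3, 60, fx.life_table)
        assert T[space.death_sb, space.death_sb] == 1.0
        assert T[space.death_other, space.death_other] == 1.0

    def test_tunnel_rows_have_no_self_transition(self, ps, fx):
        space = build_state_space()
        T = build_transition_matrix(ps, Technique.CRT3D, 0, 60, fx.life_table)
        for level in range(1, 5):
            i = space.recurrent(level)
            assert T[i, i] == 0.0


class TestRunCohort:
    def test_zero_toxicity_reproduces_life_table_survival(self, ps, fx):
        trace = run_cohort(zero_toxicity(ps), Technique.CRT3D, 40, fx.life_table)
        space = trace.space
        alive = trace.occupancy[0, :, space.alive].sum(axis=0)
        expected = np.cumprod(
            np.concatenate(
                [[1.0], 1.0 - fx.life_table.half_cycle_q(trace.ages[0])]
            )
        )
        assert np.allclose(alive, expected, atol=1e-12)
        assert trace.occupancy[0, :, space.death_sb].max() == 0.0

    def test_mass_conserved_every_cycle(self, ps, fx):
        trace = run_cohort(ps, Technique.CRT3D, 60, fx.life_table)
        totals = trace.occupancy[0].sum(axis=1)
        assert np.allclose(totals, 1.0, atol=1e-9)
        # deaths + alive account for everyone
        assert np.all(trace.occupancy[0] >= -1e-15)

    def test_absorbing_occupancy_non_decreasing(self, ps, fx):
        trace = run_cohort(ps, Technique.CRT3D, 60, fx.life_table)
        for state in (trace.space.death_sb, trace.space.death_other):
            occ = trace.occupancy[0, :, state]
            assert np.all(np.diff(occ) >= -1e-12)

    def test_tunnel_occupancy_equals_previous_inflow(self, ps, fx):
        trace = run_cohort(ps, Technique.CRT3D, 55, fx.life_table)
        space = trace.space
        re_idx = [space.recurrent(l) for l in range(1, 5)]
        tunnel = trace.occupancy[0, :, re_idx].sum(axis=0)
        inflow = trace.flows["recurrences"][0]
        # occupancy at cycle k+1 is exactly the recurrence inflow during cycle k
        assert np.allclose(tunnel[1:], inflow, atol=1e-12)

    def test_matches_explicit_matrix_propagation(self, ps, fx):
        """The vectorized engine equals step-by-step multiplication with the
        explicit transition matrices."""
        start_age = 70.0
        trace = run_cohort(ps, Technique.IMRT, start_age, fx.life_table)
        dyn = build_dynamics(ps, Technique.IMRT)
        x = np.zeros(trace.space.n)
        x[trace.space.post_treatment] = 1.0
        for k in range(trace.n_cycles):
            T = transition_matrix(dyn, k, start_age + k * 0.5, fx.life_table)
            x = x @ T
            assert np.allclose(x, trace.occupancy[0, k + 1], atol=1e-12)

    def test_start_age_bounds(self, ps, fx):
        with pytest.raises(ValueError):
            run_cohort(ps, Technique.IMRT, 20, fx.life_table)
        with pytest.raises(ValueError):
            run_cohort(ps, Technique.IMRT, 70, fx.life_table, horizon_age=60)

    def test_technique_ordering_of_harms(self, ps, fx):
        """More conformal techniques never increase hospitalizations or deaths."""
        cums = {}
        for tech in Technique:
            tr = run_cohort(ps, tech, 50, fx.life_table)
            cums[tech] = (
                np.cumsum(tr.aggregate_flow("hospitalizations")),
                np.cumsum(tr.aggregate_flow("death_sb")),
            )
        for i in range(2):
            assert np.all(
                cums[Technique.IMRT_IGRT][i] <= cums[Technique.IMRT][i] + 1e-15
            )
            assert np.all(cums[Technique.IMRT][i] <= cums[Technique.CRT3D][i] + 1e-15)


class TestMixedCohort:
    def test_single_age_equals_run_cohort(self, ps, fx):
        mix = pd.DataFrame({"age": [70], "weight": [1.0]})
        mixed = run_mixed_cohort(ps, Technique.CRT3D, mix, fx.life_table)
        single = run_cohort(ps, Technique.CRT3D, 70, fx.life_table)
        assert np.allclose(
            mixed.aggregate_flow("hospitalizations"),
            single.aggregate_flow("hospitalizations"),
            atol=1e-15,
        )

    def test_two_ages_average_linearly(self, ps, fx):
        mix = pd.DataFrame({"age": [50, 70], "weight": [0.5, 0.5]})
        mixed = run_mixed_cohort(ps, Technique.IMRT, mix, fx.life_table)
        singles = [run_cohort(ps, Technique.IMRT, a, fx.life_table) for a in (50, 70)]
        C = mixed.n_cycles
        expected = 0.5 * sum(
            np.pad(s.aggregate_flow("death_sb"), (0, C - s.n_cycles)) for s in singles
        )
        assert np.allclose(mixed.aggregate_flow("death_sb"), expected, atol=1e-12)

    def test_unnormalized_weights_rejected(self, ps, fx):
        mix = pd.DataFrame({"age": [50, 70], "weight": [0.5, 0.4]})
        with pytest.raises(ValueError):
            run_mixed_cohort(ps, Technique.IMRT, mix, fx.life_table)
        mix = pd.DataFrame({"age": [50, 70], "weight": [1.5, -0.5]})
        with pytest.raises(ValueError):
            run_mixed_cohort(ps, Technique.IMRT, mix, fx.life_table)


def _microsimulate(ps, technique, start_age, life_table, n_patients, seed, cycles):
    """Individual-level stochastic counterpart of the cohort engine."""
    dyn = build_dynamics(ps, technique)
    space = dyn.space
    rng = np.random.default_rng(seed)
    states = np.zeros(n_patients, dtype=np.int64)
    snapshots = {}
    for k in range(max(cycles)):
        T = transition_matrix(dyn, k, start_age + k * 0.5, life_table)
        cum = np.cumsum(T, axis=1)
        cum[:, -1] = 1.0
        u = rng.random(n_patients)
        states = (u[:, None] > cum[states]).sum(axis=1)
        if k + 1 in cycles:
            snapshots[k + 1] = np.bincount(states, minlength=space.n) / n_patients
    return snapshots


def test_cohort_trace_matches_microsimulation(ps, fx):
    """Expected occupancy equals the mean of 50,000 simulated patients within 3 SE."""
    n = 50_000
    checkpoints = (10, 40, 100)
    trace = run_cohort(ps, Technique.CRT3D, 30, fx.life_table)
    sims = _microsimulate(ps, Technique.CRT3D, 30, fx.life_table, n, 2024, checkpoints)
    for k, sim in sims.items():
        expected = trace.occupancy[0, k]
        se = np.sqrt(np.maximum(expected * (1 - expected), 1e-9) / n)
        assert np.all(np.abs(sim - expected) <= 3 * se + 2.0 / n)
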