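"""Cohort engine: cycle operators, conservation, closed-form checks."""

import numpy as np
import pytest

from oamodel.cohort import CohortSpec, build_cohort
from oamodel.economics import evaluate_arm
from oamodel.engine import (
    EXERCISE,
    USUAL_CARE,
    Trajectory,
    build_cycle_matrix,
    half_cycle_occupancy,
    initial_occupancy,
    run_arm,
)
from oamodel.states import DEAD, N_PAIN, N_STATES, idx_pp, idx_pre

from helpers import degenerate as _degenerate, single_stratum_cohort as _single_stratum_cohort


def test_cycle_matrix_rows_sum_to_one(paper_like):
    for stratum in paper_like.strata[::3]:
        for arm in (USUAL_CARE, EXERCISE):
            for cycle in (1, 2, 10, 40):
                op = build_cycle_matrix(stratum, arm, cycle, paper_like)
                assert np.allclose(op.matrix.sum(axis=1), 1.0, atol=1e-12)
                assert np.all(op.matrix >= 0.0)


def test_zero_hazards_preserve_alive_pain_mass(paper_like):
    """With all hazards zero the operator moves no mass to death and keeps
    the pain distribution fixed (tunnel year advances only)."""
    inputs = _degenerate(paper_like, q=0.0, uptake=(0.0, 0.0), revision=0.0)
    stratum = inputs.strata[0]
    op = build_cycle_matrix(stratum, EXERCISE, 5, inputs)
    assert np.all(op.matrix[: N_STATES - 1, DEAD] == 0.0)
    occ = np.zeros(N_STATES)
    occ[idx_pre(0, 1)] = 0.3
    occ[idx_pp(3, 2)] = 0.7
    out = occ @ op.matrix
    assert out[idx_pre(0, 1)] == pytest.approx(0.3)
    assert out[idx_pp(4, 2)] == pytest.approx(0.7)


def test_pure_mortality_splits_mass():
    """q = 0.01, no uptake: 0.99 stays alive, 0.01 moves to dead."""
    from oamodel.synthetic import ScenarioConfig, generate_input_bundle

    inputs = _degenerate(
        generate_input_bundle(ScenarioConfig(seed=5)), q=0.01, uptake=(0.0, 0.0)
    )
    stratum = inputs.strata[0]
    op = build_cycle_matrix(stratum, EXERCISE, 3, inputs)
    i = idx_pre(1, 1)
    assert op.matrix[i, DEAD] == pytest.approx(0.01, abs=1e-15)
    assert op.matrix[i, i] == pytest.approx(0.99, abs=1e-15)


def test_cumulative_uptake_matches_closed_form(paper_like):
    """No deaths: cumulative conversion by year 10 is 1 - 0.74 * 0.92^9."""
    inputs = _degenerate(paper_like, q=0.0)
    cohort = _single_stratum_cohort(inputs, n=1.0)
    traj = run_arm(EXERCISE, cohort, inputs, horizon=10)[inputs.strata[0].key]
    cumulative = traj.primaries.sum()
    assert cumulative == pytest.approx(1.0 - 0.74 * 0.92**9, abs=1e-12)


def test_usual_care_cycle_one_is_single_matrix_product(paper_like):
    """No death/revision: cycle-1 occupancy = baseline x post-op transition."""
    inputs = _degenerate(paper_like, q=0.0)
    key = inputs.strata[0].key
    props = np.array([0.2, 0.5, 0.3])
    cohort = _single_stratum_cohort(inputs, n=1.0, props=props)
    traj = run_arm(USUAL_CARE, cohort, inputs, horizon=1)[key]
    expected = props @ inputs.transitions[("post_tkr", key)]
    got = np.array([traj.occupancy[1, idx_pp(1, p)] for p in range(N_PAIN)])
    assert np.allclose(got, expected, atol=1e-12)
    assert traj.primaries[0] == pytest.approx(1.0)


def test_exercise_without_uptake_never_operates(paper_like):
    inputs = _degenerate(paper_like, q=0.0, uptake=(0.0, 0.0))
    cohort = _single_stratum_cohort(inputs)
    traj = run_arm(EXERCISE, cohort, inputs, horizon=20)[inputs.strata[0].key]
    assert np.all(traj.primaries == 0.0)


def test_mass_conservation_every_cycle(paper_like, paper_cohort):
    for arm in (USUAL_CARE, EXERCISE):
        for key, traj in run_arm(arm, paper_cohort, paper_like).items():
            totals = traj.occupancy.sum(axis=1)
            n0 = paper_cohort.n_eligible[key]
            assert np.allclose(totals, n0, rtol=1e-9)


def test_event_monotonicity_and_bounds(paper_like, paper_cohort):
    for key, traj in run_arm(EXERCISE, paper_cohort, paper_like).items():
        assert np.all(traj.deaths >= 0)
        assert np.all(traj.primaries >= 0)
        cum_primaries = traj.primaries.cumsum()
        assert np.all(np.diff(cum_primaries) >= 0)
        assert cum_primaries[-1] <= paper_cohort.n_eligible[key] + 1e-9
        # everyone is dead at lifetime end
        assert traj.occupancy[-1, DEAD] == pytest.approx(
            paper_cohort.n_eligible[key], rel=1e-9
        )


def test_half_cycle_is_trapezoid(paper_like):
    stratum = paper_like.strata[0]
    occ = np.zeros((3, N_STATES))
    occ[0, idx_pre(0, 0)] = 1.0
    occ[1, idx_pre(0, 0)] = 0.9
    occ[2, idx_pre(0, 0)] = 0.9
    traj = Trajectory(stratum, EXERCISE, occ, np.zeros(2), np.zeros(2), np.zeros(2))
    eff = half_cycle_occupancy(traj)
    assert eff[0, idx_pre(0, 0)] == pytest.approx(0.95)
    assert eff[1, idx_pre(0, 0)] == pytest.approx(0.9)  # constant: unchanged


def test_trapezoid_equals_exact_integral_for_linear_decline(paper_like):
    """Occupancy declining linearly: trapezoidal accrual = exact integral."""
    stratum = paper_like.strata[0]
    n_cycles = 10
    levels = np.linspace(1.0, 0.0, n_cycles + 1)
    occ = np.zeros((n_cycles + 1, N_STATES))
    occ[:, idx_pre(0, 0)] = levels
    occ[:, DEAD] = 1.0 - levels
    traj = Trajectory(
        stratum, EXERCISE, occ, np.zeros(n_cycles), np.zeros(n_cycles), np.zeros(n_cycles)
    )
    accrued = half_cycle_occupancy(traj)[:, idx_pre(0, 0)].sum()
    exact = np.trapezoid(levels, dx=1.0)
    assert accrued == pytest.approx(exact, abs=1e-12)


def test_life_years_match_geometric_closed_form(paper_like):
    """Constant q, utility 1, no discount: life-years are the trapezoid-
    corrected geometric sum, to 1e-9."""
    s = 1.0 - 0.02
    inputs = _degenerate(
        paper_like, q=0.02, uptake=(0.0, 0.0), utility=1.0, discount=0.0
    )
    cohort = _single_stratum_cohort(inputs, n=1.0)
    horizon = 15
    arm = evaluate_arm(EXERCISE, cohort, inputs, horizon=horizon)
    expected = sum(0.5 * (s ** (t - 1) + s**t) for t in range(1, horizon + 1))
    assert arm.total_life_years == pytest.approx(expected, abs=1e-9)
    assert arm.total_qalys == pytest.approx(expected, abs=1e-9)


def test_long_horizon_truncated_to_lifetime(paper_like, paper_cohort):
    key = paper_like.strata[0].key
    traj = run_arm(EXERCISE, paper_cohort, paper_like, horizon=500)[key]
    lifetime = paper_like.econ.max_age - paper_like.stratum(key).start_age + 1
    assert traj.n_cycles == lifetime


def test_initial_occupancy_places_origin_states():
    occ = initial_occupancy(np.array([1.0, 2.0, 3.0]))
    assert occ[idx_pre(0, 0)] == 1.0
    assert occ[idx_pre(1, 1)] == 2.0
    assert occ[idx_pre(2, 2)] == 3.0
    assert occ.sum() == 6.0
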