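"""Economics layer: discounting, accrual, INMB/ICER, horizon sweep."""

import numpy as np
import pytest

from oamodel.economics import (
    compute_inmb,
    convert_currency,
    crossover_horizon,
    discount_factor,
    evaluate_arm,
    horizon_sweep,
    run_base_case,
)
from oamodel.engine import EXERCISE, USUAL_CARE
from oamodel.cohort import build_cohort

from helpers import degenerate, single_stratum_cohort


@pytest.mark.parametrize(
    "rate, cycle, expected",
    [(0.05, 1, 1.0), (0.05, 4, 1.05**-3), (0.0, 17, 1.0), (0.05, 2, 1 / 1.05)],
)
def test_discount_factor_closed_form(rate, cycle, expected):
    assert discount_factor(rate, cycle) == pytest.approx(expected, rel=1e-12)


def test_discount_factor_rejects_cycle_zero():
    with pytest.raises(ValueError):
        discount_factor(0.05, 0)


def test_one_cycle_survivor_accrues_full_utility(paper_like):
    """One person at utility 0.8, no events, no discounting: 0.8 QALYs per
    survived cycle; the final (death) cycle accrues half under the trapezoid."""
    inputs = degenerate(
        paper_like, q=0.0, uptake=(0.0, 0.0), utility=0.8, discount=0.0
    )
    cohort = single_stratum_cohort(inputs, n=1.0)
    arm = evaluate_arm(EXERCISE, cohort, inputs, horizon=1)
    assert arm.total_qalys == pytest.approx(0.8, abs=1e-12)
    # same person dying within the cycle accrues half
    dying = degenerate(
        paper_like, q=1.0 - 1e-12, uptake=(0.0, 0.0), utility=0.8, discount=0.0
    )
    arm = evaluate_arm(EXERCISE, cohort, dying, horizon=1)
    assert arm.total_qalys == pytest.approx(0.4, abs=1e-9)


def test_usual_care_charges_exactly_one_primary_procedure(paper_like):
    """Usual care, one person, no death: cycle-1 cost is one primary TKR."""
    inputs = degenerate(paper_like, q=0.0)
    cohort = single_stratum_cohort(inputs, n=1.0)
    arm = evaluate_arm(USUAL_CARE, cohort, inputs, horizon=1)
    primary, _ = inputs.effective_costs()
    assert arm.total_cost == pytest.approx(primary, rel=1e-12)
    assert arm.total_primaries == pytest.approx(1.0)


def test_exercise_without_conversion_costs_program_only(paper_like):
    inputs = degenerate(paper_like, uptake=(0.0, 0.0), revision=0.0)
    cohort = single_stratum_cohort(inputs, n=1.0)
    arm = evaluate_arm(EXERCISE, cohort, inputs)
    assert arm.total_cost == pytest.approx(
        inputs.costs.nonsurgical_program, rel=1e-12
    )


def test_inmb_reproduces_published_base_case():
    """Published base case: dC = -A$7970 pp, dE = -26412/61394 -> ~ -A$4090."""
    inmb = compute_inmb(-489_307_942 / 61_394, -26_412 / 61_394, 28_033.0)
    assert inmb == pytest.approx(-4090, abs=1.0)
    assert compute_inmb(0.0, 0.0, 28_033.0) == 0.0
    assert compute_inmb(-10.0, 0.0, 1.0) == 10.0
    assert compute_inmb(-10.0, 0.0, 1e6) == 10.0


@pytest.mark.parametrize(
    "aud, usd",
    [(24_607, 17_095), (43_125, 29_959), (28_033, 19_475)],
)
def test_currency_conversion_matches_published(aud, usd):
    assert convert_currency(aud, 0.6947) == pytest.approx(usd, abs=1.0)


def test_currency_conversion_degenerate():
    assert convert_currency(0.0, 0.6947) == 0.0
    with pytest.raises(ValueError):
        convert_currency(1.0, 0.0)


def test_inmb_identity_holds_to_machine_precision(base_result):
    res = base_result
    n = res.n
    assert res.inmb_per_person == pytest.approx(
        res.wtp * res.delta_qalys / n - res.delta_cost / n, abs=1e-9
    )


def test_discounting_never_increases_totals(paper_like, paper_cohort):
    undisc = paper_like.clone()
    undisc.settings.econ.discount_rate = 0.0
    for arm in (USUAL_CARE, EXERCISE):
        disc = evaluate_arm(arm, paper_cohort, paper_like)
        flat = evaluate_arm(arm, paper_cohort, undisc)
        assert disc.total_cost <= flat.total_cost
        assert disc.total_qalys <= flat.total_qalys


def test_icer_suppressed_in_southwest_quadrant(base_result):
    assert base_result.delta_cost < 0 and base_result.delta_qalys < 0
    assert base_result.icer is None
    assert base_result.inmb_per_person != 0.0


def test_null_effect_horizon_curve_is_pure_cost_saving(null_inputs):
    """Identical arms: INMB(h) = -dCost(h) at every horizon and stays
    positive (the program is cheaper at every truncation)."""
    cohort = build_cohort(null_inputs)
    res = run_base_case(null_inputs, cohort)
    sweep = horizon_sweep(res)
    assert np.allclose(
        sweep["inmb_per_person"], -sweep["delta_cost_per_person"], atol=1e-6
    )
    assert (sweep["inmb_per_person"] > 0).all()
    assert crossover_horizon(sweep) == sweep["horizon"].max()


def test_horizon_sweep_matches_brute_force_truncation(base_result):
    """Each sweep point equals a brute-force truncated recomputation from
    the per-cycle streams, and the crossover is the last nonnegative point."""
    res = base_result
    sweep = horizon_sweep(res)
    n = res.n
    wtp = res.wtp
    h_max = len(sweep)
    for h in (1, 3, 9, h_max):
        dc = (res.exercise.cost[:h].sum() - res.usual_care.cost[:h].sum()) / n
        de = (res.exercise.qalys[:h].sum() - res.usual_care.qalys[:h].sum()) / n
        row = sweep.iloc[h - 1]
        assert row["inmb_per_person"] == pytest.approx(wtp * de - dc, abs=1e-9)
    cross = crossover_horizon(sweep)
    assert cross is not None
    assert sweep.iloc[cross - 1]["inmb_per_person"] >= 0
    if cross < h_max:
        assert sweep.iloc[cross]["inmb_per_person"] < 0


def test_horizon_sweep_monotone_for_front_loaded_costs(paper_like):
    """Front-loaded surgical cost with a slowly accruing QALY advantage and
    no late-life mortality divergence between arms: INMB(h) never rises.
    (Brute force over every horizon; the program moves nobody between pain
    states, so each extra year only adds conversion costs and the
    non-converters' utility shortfall.)"""
    inputs = degenerate(paper_like, q=0.02, revision=0.0)
    for key in [s.key for s in inputs.strata]:
        inputs.transitions[("exercise", key)] = np.eye(3)
    cohort = build_cohort(inputs)
    sweep = horizon_sweep(run_base_case(inputs, cohort))
    assert np.all(np.diff(sweep["inmb_per_person"]) <= 1e-9)


def test_per_person_times_n_equals_cohort_total(base_result):
    pp = base_result.per_person()
    tot = base_result.cohort_total()
    for field in pp:
        assert pp[field] * base_result.n == pytest.approx(tot[field], rel=1e-9)
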