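"""DSA and PSA: determinism, brute-force CEAC, convergence of input draws."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oamodel.cohort import build_cohort
from oamodel.economics import run_base_case
from oamodel.sensitivity import (
    Parameter,
    ceac,
    default_parameters,
    one_way_dsa,
    run_psa,
    sample_draw,
    _rng_for,
)
from oamodel.synthetic import ScenarioConfig, generate_input_bundle


@pytest.fixture(scope="module")
def small_psa(small_inputs):
    return run_psa(small_inputs, n_sims=60, seed=42)


def test_degenerate_parameter_has_zero_span(small_inputs):
    base = small_inputs.settings.uptake.p_tkr_year1
    tor = one_way_dsa(
        small_inputs,
        parameters=[Parameter("noop", "settings.uptake.p_tkr_year1", base, base)],
    )
    assert tor.loc[0, "span"] == pytest.approx(0.0, abs=1e-9)
    assert tor.loc[0, "inmb_low"] == tor.loc[0, "inmb_high"]


def test_program_cost_sweep_shifts_inmb_by_exact_difference(small_inputs):
    """The program is a one-off, undiscounted, universal cost: sweeping it
    from A$750 to A$3000 moves the per-person INMB by exactly A$2250."""
    tor = one_way_dsa(
        small_inputs,
        parameters=[
            Parameter("program_cost", "settings.costs.nonsurgical_program", 750.0, 3000.0)
        ],
    )
    assert tor.loc[0, "inmb_low"] - tor.loc[0, "inmb_high"] == pytest.approx(
        2250.0, abs=1e-9
    )


def test_tornado_sorted_and_program_utility_dominant(paper_like, paper_cohort):
    """The exercise-arm quality-of-life parameter is a dominant driver of
    cost-effectiveness: top-two span, well clear of the median parameter."""
    tor = one_way_dsa(paper_like, paper_cohort)
    assert (tor["span"].diff().dropna() <= 1e-9).all()  # sorted descending
    rank = tor.index[tor["parameter"] == "exercise_arm_utility"][0]
    assert rank <= 1
    assert tor.loc[rank, "span"] > 3.0 * tor["span"].median()


def test_probability_bounds_are_clipped(small_inputs):
    tor = one_way_dsa(
        small_inputs,
        parameters=[
            Parameter(
                "uptake", "settings.uptake.p_tkr_year1", -0.2, 1.4, is_probability=True
            )
        ],
    )
    assert np.isfinite(tor.loc[0, "inmb_low"]) and np.isfinite(tor.loc[0, "inmb_high"])


def test_default_parameter_bounds_bracket_base(paper_like):
    for p in default_parameters(paper_like):
        assert p.low < p.high


def test_psa_is_deterministic_under_fixed_seed(small_inputs):
    a = run_psa(small_inputs, n_sims=12, seed=7)
    b = run_psa(small_inputs, n_sims=12, seed=7)
    pd.testing.assert_frame_equal(a.draws, b.draws)
    assert a.mean_inmb == b.mean_inmb and a.ci_inmb == b.ci_inmb


def test_psa_seed_changes_draws(small_inputs):
    a = run_psa(small_inputs, n_sims=8, seed=7)
    b = run_psa(small_inputs, n_sims=8, seed=8)
    assert not np.allclose(a.draws["inmb"], b.draws["inmb"])


def test_parameter_streams_independent_of_added_parameters():
    """Streams are keyed by (seed, draw, path): the same path gives the
    same numbers regardless of what else is sampled."""
    a = _rng_for(3, 5, "settings.uptake.p_tkr_year1").random(4)
    b = _rng_for(3, 5, "settings.uptake.p_tkr_year1").random(4)
    c = _rng_for(3, 5, "settings.costs.primary_tkr").random(4)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_all_fixed_specs_reproduce_base_case():
    """Zero-dispersion settings degenerate every family to 'fixed': each
    draw equals the base case."""
    cfg = ScenarioConfig(
        seed=11,
        n_strata_override=2,
        max_age=75,
        settings_overrides={
            "uptake": {
                "p_tkr_year1_ci": [0.26, 0.26],
                "p_tkr_subsequent_ci": [0.08, 0.08],
            },
            "costs": {
                "surgical_se_frac": 0.0,
                "nonsurgical_low": 1500,
                "nonsurgical_high": 1500,
            },
            "revision_disutility": {"se_frac": 0.0},
            "psa": {
                "excess_ratio_sdlog": 0.0,
                "mortality_sdlog": 0.0,
                "revision_prob_n_effective": 0.0,
            },
        },
    )
    inputs = generate_input_bundle(cfg)
    for k in inputs.baseline_n_eff:
        inputs.baseline_n_eff[k] = 0.0
    for k in inputs.transition_n_eff:
        inputs.transition_n_eff[k] = inputs.transition_n_eff[k] * 0.0
    base = run_base_case(inputs, build_cohort(inputs)).per_person()
    psa = run_psa(inputs, n_sims=5, seed=3)
    assert np.allclose(psa.draws["inmb"], base["inmb"], atol=1e-9)
    assert np.allclose(psa.draws["delta_cost"], base["delta_cost"], atol=1e-9)


def test_psa_input_draws_converge_to_base_means(small_inputs):
    """Mean of 10 000 sampled values of each scalar input lies within 3 SE
    of its base-case value."""
    from oamodel.distributions import (
        fit_beta_from_ci,
        fit_gamma_from_mean_se,
        lognormal_for_ratio,
    )

    u = small_inputs.uptake
    primary, _ = small_inputs.effective_costs()
    specs = {
        "uptake_year1": (fit_beta_from_ci(u.p_tkr_year1, *u.p_tkr_year1_ci), u.p_tkr_year1),
        "primary_cost": (
            fit_gamma_from_mean_se(primary, 0.15 * primary),
            primary,
        ),
        "excess_ratio": (lognormal_for_ratio(0.55, 0.1), 0.55),
    }
    n = 10_000
    for name, (spec, base) in specs.items():
        rng = np.random.default_rng(101)
        draws = np.array([spec.sample(rng) for _ in range(n)])
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - base) < 3 * se, name


def test_psa_mean_inmb_stable_across_sample_sizes(small_inputs, small_psa):
    """60-draw mean INMB within 3 Monte Carlo SEs of a 400-draw rerun."""
    big = run_psa(small_inputs, n_sims=400, seed=1)
    se = np.hypot(
        small_psa.draws["inmb"].std(ddof=1) / np.sqrt(small_psa.n_sims),
        big.draws["inmb"].std(ddof=1) / np.sqrt(big.n_sims),
    )
    assert abs(small_psa.mean_inmb - big.mean_inmb) < 3 * se


def test_ceac_equals_brute_force_counting(small_psa):
    curve = small_psa.ceac
    draws = small_psa.draws
    for _, row in curve.iloc[::10].iterrows():
        lam = row["threshold"]
        count = sum(
            1
            for _, d in draws.iterrows()
            if lam * d["delta_qalys"] - d["delta_cost"] > 0
        )
        assert row["fraction_cost_effective"] == pytest.approx(count / len(draws))


def test_ceac_degenerate_draw_sets():
    saving = pd.DataFrame({"delta_cost": [-10.0] * 4, "delta_qalys": [0.0] * 4})
    costing = pd.DataFrame({"delta_cost": [10.0] * 4, "delta_qalys": [0.0] * 4})
    mixed = pd.concat([saving, costing], ignore_index=True)
    assert (ceac(saving, wtp=28_033)["fraction_cost_effective"] == 1.0).all()
    assert (ceac(costing, wtp=28_033)["fraction_cost_effective"] == 0.0).all()
    assert (ceac(mixed, wtp=28_033)["fraction_cost_effective"] == 0.5).all()


@settings(deadline=None, max_examples=40)
@given(
    de=st.lists(st.floats(0.01, 2.0), min_size=3, max_size=20),
    dc=st.lists(st.floats(-5e4, 5e4), min_size=3, max_size=20),
)
def test_ceac_monotone_when_all_qaly_gains_positive(de, dc):
    m = min(len(de), len(dc))
    draws = pd.DataFrame({"delta_cost": dc[:m], "delta_qalys": de[:m]})
    curve = ceac(draws, wtp=28_033)["fraction_cost_effective"].to_numpy()
    assert np.all(np.diff(curve) >= 0)


def test_quadrant_fractions_sum_to_one(small_psa):
    assert sum(small_psa.quadrant_fractions.values()) == pytest.approx(1.0)
    assert all(0.0 <= v <= 1.0 for v in small_psa.quadrant_fractions.values())
    assert small_psa.ci_inmb[0] <= small_psa.mean_inmb <= small_psa.ci_inmb[1]
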