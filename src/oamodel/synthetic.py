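"""Synthetic input bundles emulating the registry-derived study inputs.

The real model inputs are stratified registry and statistical-agency
tables (joint-replacement registry outcomes, national life tables,
hospital costing data) that are not redistributable.  This module
generates bundles with the same structure and realistic magnitudes so
that every downstream stage is runnable and testable:

* eight (age band x sex) strata whose eligible-cohort total is of the
  order of the ~61 000 primary knee replacements performed nationally in
  the index year;
* Gompertz all-cause mortality calibrated to female/male life
  expectancies at 65 of about 22 and 19 years;
* post-surgical excess-mortality ratios below 1 for the first 9 years
  and above 1 beyond 12 years;
* post-operative pain transitions concentrating in the no/mild state,
  with the exercise-program transitions improving less on average;
* Dirichlet-style baseline pain-state proportions with pseudo-counts.

Three effect profiles are provided: ``paper_like`` (defaults above),
``null_effect`` (arms identical except costs — used for symmetry tests)
and ``extreme_benefit``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .inputs import (
    CONTEXTS,
    HOSPITALS,
    ModelInputs,
    Settings,
    write_bundle,
)
from .states import AGE_BANDS, K_MAX, N_PAIN, SEXES, default_strata

PROFILES = ("paper_like", "null_effect", "extreme_benefit")

# plausible national population counts (persons) by band and sex
_POPULATION = {
    ("45-54", "female"): 1_630_000.0,
    ("45-54", "male"): 1_580_000.0,
    ("55-64", "female"): 1_500_000.0,
    ("55-64", "male"): 1_410_000.0,
    ("65-74", "female"): 1_270_000.0,
    ("65-74", "male"): 1_180_000.0,
    ("75-84", "female"): 800_000.0,
    ("75-84", "male"): 700_000.0,
}

# annual primary-replacement rates per person, peaking at 65-74
_BAND_RATE = {"45-54": 0.0012, "55-64": 0.0056, "65-74": 0.0106, "75-84": 0.0096}
_SEX_RATE_FACTOR = {"female": 1.08, "male": 0.92}

# reference pain-state mixes and utilities (no/mild, moderate, severe/extreme)
_BASELINE_MIX = np.array([0.20, 0.50, 0.30])
_U_BASE = np.array([0.72, 0.55, 0.35])
_U_POST = np.array([0.85, 0.68, 0.48])

_P_TKR = np.array(
    [
        [0.90, 0.08, 0.02],
        [0.75, 0.20, 0.05],
        [0.65, 0.25, 0.10],
    ]
)
_P_EXERCISE = np.array(
    [
        [0.70, 0.25, 0.05],
        [0.35, 0.50, 0.15],
        [0.15, 0.45, 0.40],
    ]
)

_EXCESS_INTERVALS = [(1, 4, 0.55), (5, 9, 0.80), (10, 12, 1.00), (13, None, 1.25)]

_GOMPERTZ_B = {"female": 0.097, "male": 0.094}
_LIFE_EXPECTANCY_65 = {"female": 22.0, "male": 19.0}

_REVISION_AGE_FACTOR = {"45-54": 1.8, "55-64": 1.3, "65-74": 0.9, "75-84": 0.6}


@dataclass
class ScenarioConfig:
    """Configuration for one synthetic bundle; the seed fixes every number."""

    seed: int = 0
    profile: str = "paper_like"
    tkr_rate_scale: float = 1.0
    n_strata_override: int | None = None
    mortality_shape: dict[str, tuple[float, float]] | None = None  # sex -> (a, b)
    max_age: int = 100
    discount_rate: float = 0.05
    settings_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}; choose from {PROFILES}")


def gompertz_q(ages: np.ndarray, a: float, b: float) -> np.ndarray:
    """Annual death probability q(age) = 1 - exp(-a * e^(b*age))."""
    return 1.0 - np.exp(-a * np.exp(b * ages))


def _life_expectancy_at(age: int, a: float, b: float, top: int = 110) -> float:
    ages = np.arange(age, top + 1)
    q = gompertz_q(ages, a, b)
    surv = np.concatenate([[1.0], np.cumprod(1.0 - q)])
    return float(np.sum(0.5 * (surv[:-1] + surv[1:])))


def calibrate_gompertz(sex: str) -> tuple[float, float]:
    """Choose the Gompertz level ``a`` to hit the target life expectancy at 65."""
    b = _GOMPERTZ_B[sex]
    target = _LIFE_EXPECTANCY_65[sex]
    lo, hi = 1e-9, 1e-2
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if _life_expectancy_at(65, mid, b) > target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi)), b


def _perturb_row(row: np.ndarray, rng: np.random.Generator, scale: float) -> np.ndarray:
    noisy = row * np.exp(rng.normal(0.0, scale, size=row.shape))
    return noisy / noisy.sum()


def _revision_hazard(rng: np.random.Generator, band: str, sex: str) -> np.ndarray:
    years = np.arange(1, K_MAX + 1)
    base = 0.0025 + 0.0055 * np.exp(-0.35 * (years - 1))
    factor = _REVISION_AGE_FACTOR[band] * (1.1 if sex == "male" else 1.0)
    jitter = np.exp(rng.normal(0.0, 0.05, size=K_MAX))
    return np.clip(base * factor * jitter, 0.0, 0.5)


def generate_input_bundle(
    config: ScenarioConfig, out: str | Path | None = None
) -> ModelInputs:
    """Generate (and optionally write) a validated synthetic bundle."""
    rng = np.random.default_rng(config.seed)
    null = config.profile == "null_effect"
    extreme = config.profile == "extreme_benefit"

    settings = Settings.model_validate(
        {
            "econ": {
                "discount_rate": config.discount_rate,
                "max_age": config.max_age,
            },
            **config.settings_overrides,
        }
    )
    if null:
        settings.revision_disutility.event = 0.0
        settings.revision_disutility.chronic = 0.0

    strata = default_strata(settings.econ.start_age_offset)
    if config.n_strata_override is not None:
        strata = strata[: config.n_strata_override]
    keys = [s.key for s in strata]

    population = {k: _POPULATION[k] for k in keys}
    tkr_rate = {
        (band, sex): _BAND_RATE[band] * _SEX_RATE_FACTOR[sex] * config.tkr_rate_scale
        for (band, sex) in keys
    }

    # mortality: smooth calibrated Gompertz (monotone by construction)
    mortality_q = {}
    ages = np.arange(45, settings.econ.max_age + 1)
    for sex in SEXES:
        if config.mortality_shape and sex in config.mortality_shape:
            a, b = config.mortality_shape[sex]
        else:
            a, b = calibrate_gompertz(sex)
        mortality_q[sex] = np.clip(gompertz_q(ages, a, b), 0.0, 0.999999)

    excess = (
        [(1, None, 1.0)] if null else [tuple(iv) for iv in _EXCESS_INTERVALS]
    )

    # baseline pain-state mixes by stratum and hospital type
    baseline_props, baseline_n_eff = {}, {}
    cohort_sizes = {k: population[k] * tkr_rate[k] for k in keys}
    total_cohort = sum(cohort_sizes.values())
    mix_public = settings.hospital_mix_public
    prom_n_total = 9889.0  # registry patient-reported-outcome sample size
    for key in keys:
        band, sex = key
        for h in HOSPITALS:
            target = _BASELINE_MIX.copy()
            if sex == "male":
                target[0] *= 1.25  # more no/mild pain at baseline in males
            if h == "private":
                target[0] *= 1.3
            target = target / target.sum()
            props = _perturb_row(target, rng, 0.05)
            share = mix_public if h == "public" else 1.0 - mix_public
            n_eff = max(30.0, round(prom_n_total * share * cohort_sizes[key] / total_cohort))
            baseline_props[(key, h)] = props
            baseline_n_eff[(key, h)] = float(n_eff)

    # transitions
    transitions, transition_n_eff = {}, {}
    if null:
        stationary = np.array([0.75, 0.20, 0.05])
        P_shared = np.tile(stationary, (N_PAIN, 1))
    for key in keys:
        if null:
            P_tkr = P_shared.copy()
            P_ex = P_shared.copy()
        else:
            P_tkr = np.vstack([_perturb_row(r, rng, 0.04) for r in _P_TKR])
            base_ex = (
                np.array([[0.90, 0.08, 0.02], [0.80, 0.16, 0.04], [0.70, 0.22, 0.08]])
                if extreme
                else _P_EXERCISE
            )
            P_ex = np.vstack([_perturb_row(r, rng, 0.04) for r in base_ex])
        transitions[("post_tkr", key)] = P_tkr
        transitions[("exercise", key)] = P_ex
        n_share = cohort_sizes[key] / total_cohort
        transition_n_eff[("post_tkr", key)] = np.maximum(
            50.0, np.round(prom_n_total * n_share * _BASELINE_MIX * 3)
        )
        transition_n_eff[("exercise", key)] = np.maximum(
            30.0, np.round(1500.0 * n_share * _BASELINE_MIX * 3)
        )

    revision = {key: _revision_hazard(rng, *key) for key in keys}

    # utilities: small age decrement and seeded jitter, constant under null
    utilities = {}
    for key in keys:
        band, _ = key
        age_drop = 0.004 * AGE_BANDS.index(band)
        if null:
            u_b, u_p = _U_BASE.copy(), _U_POST.copy()
        else:
            u_b = np.clip(_U_BASE - age_drop + rng.normal(0.0, 0.01, 3), -1.0, 0.95)
            u_p = np.clip(_U_POST - age_drop + rng.normal(0.0, 0.01, 3), -1.0, 0.95)
            u_p = np.maximum(u_p, u_b + 0.02)  # surgery improves within-state utility
        utilities[(key, "baseline")] = np.sort(u_b)[::-1]
        utilities[(key, "post_tkr")] = np.sort(u_p)[::-1]

    # incremental utilities for the exercise arm, keyed to state transitions
    inc = np.zeros((N_PAIN, N_PAIN))
    uplift = 0.10 if extreme else 0.03
    for o in range(N_PAIN):
        for c in range(N_PAIN):
            if null:
                # align program utilities exactly with post-surgical ones
                inc[o, c] = _U_POST[c] - _U_BASE[o]
            else:
                inc[o, c] = (_U_BASE[c] - _U_BASE[o]) + uplift

    inputs = ModelInputs(
        settings=settings,
        strata=strata,
        population=population,
        tkr_rate=tkr_rate,
        baseline_props=baseline_props,
        baseline_n_eff=baseline_n_eff,
        mortality_age_min=45,
        mortality_q=mortality_q,
        excess_intervals=excess,
        transitions=transitions,
        transition_n_eff=transition_n_eff,
        revision=revision,
        utilities=utilities,
        incremental_utility=inc,
    )
    inputs.validate()
    if out is not None:
        write_bundle(inputs, out)
    return inputs
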