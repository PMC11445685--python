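"""Deterministic (tornado) and probabilistic sensitivity analyses.

The one-way DSA reruns the model with each parameter at its lower and
upper bound (95% CI limits where reported, stated scenario ranges for
costs, +/-1.96 SE otherwise) while everything else stays at base case.

The PSA draws every uncertain input jointly from its fitted family —
Dirichlet for compositional rows, Beta for probabilities, Gamma for
costs and disutilities, log-normal for mortality ratios — reruns both
arms per draw, and summarises the per-person (dCost, dQALY, INMB)
triplets: percentile uncertainty interval, cost-effectiveness plane
quadrant fractions and the cost-effectiveness acceptability curve.

Randomness is keyed by ``(seed, draw index, parameter path)`` so adding
a parameter does not reshuffle the draws of existing ones.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortSpec, allocate_baseline_states, build_cohort, size_eligible_cohort
from .distributions import (
    DistributionSpec,
    dirichlet_from_counts,
    fit_beta_from_ci,
    fit_beta_from_mean_n,
    fit_gamma_from_mean_se,
    lognormal_for_ratio,
)
from .economics import EconResult, run_base_case
from .inputs import HOSPITALS, ModelInputs, set_target
from .states import K_MAX

log = logging.getLogger(__name__)

_Z = 1.96
_MAX_RETRIES = 100


def _rng_for(seed: int, draw: int, path: str) -> np.random.Generator:
    """Independent stream keyed by (seed, draw index, parameter path)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, draw, zlib.crc32(path.encode())])
    )


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class Parameter:
    """A scalar model input with deterministic low/high bounds."""

    name: str
    path: str
    low: float
    high: float
    is_probability: bool = False


def default_parameters(inputs: ModelInputs) -> list[Parameter]:
    """The standard one-way DSA parameter set with its bounds."""
    u = inputs.uptake
    c = inputs.costs
    du = inputs.settings.revision_disutility
    psa = inputs.settings.psa
    primary, revision = inputs.effective_costs()
    se_frac = c.surgical_se_frac
    params = [
        Parameter(
            "tkr_uptake_year1",
            "settings.uptake.p_tkr_year1",
            *u.p_tkr_year1_ci,
            is_probability=True,
        ),
        Parameter(
            "tkr_uptake_subsequent",
            "settings.uptake.p_tkr_subsequent",
            *u.p_tkr_subsequent_ci,
            is_probability=True,
        ),
        Parameter(
            "primary_tkr_cost",
            "settings.costs.primary_tkr",
            primary * (1 - _Z * se_frac),
            primary * (1 + _Z * se_frac),
        ),
        Parameter(
            "revision_tkr_cost",
            "settings.costs.revision_tkr",
            revision * (1 - _Z * se_frac),
            revision * (1 + _Z * se_frac),
        ),
        Parameter(
            "nonsurgical_program_cost",
            "settings.costs.nonsurgical_program",
            c.nonsurgical_low,
            c.nonsurgical_high,
        ),
        Parameter(
            "other_annual_costs",
            "settings.costs.other_annual_cost_delta",
            -500.0,
            500.0,
        ),
        Parameter(
            "revision_disutility_event",
            "settings.revision_disutility.event",
            du.event * (1 - _Z * du.se_frac),
            du.event * (1 + _Z * du.se_frac),
        ),
        Parameter(
            "revision_disutility_chronic",
            "settings.revision_disutility.chronic",
            du.chronic * (1 - _Z * du.se_frac),
            du.chronic * (1 + _Z * du.se_frac),
        ),
        Parameter(
            "all_cause_mortality",
            "mortality_multiplier",
            float(np.exp(-_Z * psa.mortality_sdlog)),
            float(np.exp(_Z * psa.mortality_sdlog)),
        ),
        Parameter(
            "exercise_arm_utility",
            "exercise_utility_shift",
            -_Z * psa.exercise_utility_se,
            _Z * psa.exercise_utility_se,
        ),
    ]
    for i, (lo, hi, ratio) in enumerate(inputs.excess_intervals):
        label = f"excess_mortality_years_{lo}_{hi if hi is not None else 'plus'}"
        params.append(
            Parameter(
                label,
                f"excess_ratio.{i}",
                ratio * float(np.exp(-_Z * psa.excess_ratio_sdlog)),
                ratio * float(np.exp(_Z * psa.excess_ratio_sdlog)),
            )
        )
    return params


def _apply_parameter(inputs: ModelInputs, param: Parameter, value: float) -> ModelInputs:
    clone = inputs.clone()
    if param.is_probability and not 0.0 <= value <= 1.0:
        log.warning("clipping %s bound %.4f into [0, 1]", param.name, value)
        value = float(np.clip(value, 0.0, 1.0))
    set_target(clone, param.path, value)
    return clone


def one_way_dsa(
    inputs: ModelInputs,
    cohort: CohortSpec | None = None,
    parameters: list[Parameter] | None = None,
) -> pd.DataFrame:
    """Tornado table: INMB at each parameter's bounds, sorted by span."""
    if cohort is None:
        cohort = build_cohort(inputs)
    if parameters is None:
        parameters = default_parameters(inputs)
    base = run_base_case(inputs, cohort).inmb_per_person
    rows = []
    for p in parameters:
        inmb_low = run_base_case(_apply_parameter(inputs, p, p.low), cohort).inmb_per_person
        inmb_high = run_base_case(_apply_parameter(inputs, p, p.high), cohort).inmb_per_person
        rows.append(
            {
                "parameter": p.name,
                "low": p.low,
                "high": p.high,
                "inmb_low": inmb_low,
                "inmb_high": inmb_high,
                "inmb_base": base,
                "span": abs(inmb_high - inmb_low),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("span", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PSAResult:
    """Per-draw incremental triplets and their summaries (per person)."""

    draws: pd.DataFrame  # columns: draw, delta_cost, delta_qalys, inmb
    seed: int
    wtp: float
    mean_inmb: float
    ci_inmb: tuple[float, float]
    quadrant_fractions: dict[str, float] = field(default_factory=dict)
    ceac: pd.DataFrame | None = None

    @property
    def n_sims(self) -> int:
        return len(self.draws)

    @property
    def fraction_cost_effective(self) -> float:
        return float((self.draws["inmb"] > 0).mean())


def _sample_with_retry(spec: DistributionSpec, rng: np.random.Generator, path: str):
    for attempt in range(_MAX_RETRIES):
        value = spec.sample(rng)
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if np.all(np.isfinite(arr)) and (
            spec.family != "dirichlet" or np.all(arr > 0.0)
        ):
            return value
        log.warning("redrawing invalid sample for %s (attempt %d)", path, attempt + 1)
    raise RuntimeError(f"could not draw a valid sample for {path}")


def sample_draw(inputs: ModelInputs, seed: int, draw: int) -> ModelInputs:
    """One joint PSA draw of all stochastic inputs, applied to a clone."""
    out = inputs.clone()
    psa = inputs.settings.psa

    # compositional rows: Dirichlet from pseudo-counts (a nonpositive
    # pseudo-count marks the row as having no sampling uncertainty)
    for (key, h) in list(inputs.baseline_props):
        if inputs.baseline_n_eff[(key, h)] <= 0:
            continue
        path = f"baseline_props.{key[0]}.{key[1]}.{h}"
        spec = dirichlet_from_counts(
            inputs.baseline_n_eff[(key, h)] * inputs.baseline_props[(key, h)]
        )
        out.baseline_props[(key, h)] = np.asarray(
            _sample_with_retry(spec, _rng_for(seed, draw, path), path)
        )
    for (arm, key), P in list(inputs.transitions.items()):
        n_eff = inputs.transition_n_eff[(arm, key)]
        newP = P.copy()
        for i in range(P.shape[0]):
            if n_eff[i] <= 0:
                continue
            path = f"transitions.{arm}.{key[0]}.{key[1]}.{i}"
            spec = dirichlet_from_counts(n_eff[i] * P[i])
            newP[i] = np.asarray(
                _sample_with_retry(spec, _rng_for(seed, draw, path), path)
            )
        out.transitions[(arm, key)] = newP

    # probabilities: Beta
    u = inputs.uptake
    for attr, ci in (
        ("p_tkr_year1", u.p_tkr_year1_ci),
        ("p_tkr_subsequent", u.p_tkr_subsequent_ci),
    ):
        path = f"settings.uptake.{attr}"
        spec = fit_beta_from_ci(getattr(u, attr), *ci)
        setattr(out.settings.uptake, attr, _sample_with_retry(spec, _rng_for(seed, draw, path), path))
    n_eff = psa.revision_prob_n_effective
    for key, probs in list(inputs.revision.items()) if n_eff > 0 else []:
        path = f"revision.{key[0]}.{key[1]}"
        rng = _rng_for(seed, draw, path)
        sampled = np.array(
            [
                _sample_with_retry(fit_beta_from_mean_n(p, n_eff), rng, path)
                if 0.0 < p < 1.0
                else p
                for p in probs
            ]
        )
        out.revision[key] = sampled

    # costs and disutilities: Gamma
    c = inputs.costs
    primary, revision_cost = inputs.effective_costs()
    se_program = (c.nonsurgical_high - c.nonsurgical_low) / 3.92
    for path, mean, se in (
        ("settings.costs.primary_tkr", primary, c.surgical_se_frac * primary),
        ("settings.costs.revision_tkr", revision_cost, c.surgical_se_frac * revision_cost),
        ("settings.costs.nonsurgical_program", c.nonsurgical_program, se_program),
    ):
        spec = fit_gamma_from_mean_se(mean, se)
        set_target(out, path, _sample_with_retry(spec, _rng_for(seed, draw, path), path))
    du = inputs.settings.revision_disutility
    for attr in ("event", "chronic"):
        mean = getattr(du, attr)
        if mean > 0:
            path = f"settings.revision_disutility.{attr}"
            spec = fit_gamma_from_mean_se(mean, du.se_frac * mean)
            setattr(
                out.settings.revision_disutility,
                attr,
                _sample_with_retry(spec, _rng_for(seed, draw, path), path),
            )

    # hazard ratios and mortality: log-normal multipliers
    for i, (lo, hi, ratio) in enumerate(inputs.excess_intervals):
        path = f"excess_ratio.{i}"
        spec = lognormal_for_ratio(ratio, psa.excess_ratio_sdlog)
        out.excess_intervals[i] = (
            lo,
            hi,
            float(_sample_with_retry(spec, _rng_for(seed, draw, path), path)),
        )
    for sex in inputs.mortality_q:
        path = f"mortality.{sex}"
        spec = lognormal_for_ratio(1.0, psa.mortality_sdlog)
        mult = _sample_with_retry(spec, _rng_for(seed, draw, path), path)
        out.mortality_q[sex] = np.clip(inputs.mortality_q[sex] * mult, 0.0, 0.999999)
    return out


def run_psa(
    inputs: ModelInputs,
    n_sims: int = 1000,
    seed: int = 0,
    cohort: CohortSpec | None = None,
    thresholds: np.ndarray | None = None,
) -> PSAResult:
    """Monte Carlo PSA: joint input draws, model rerun per draw."""
    base_cohort = cohort if cohort is not None else build_cohort(inputs)
    wtp = inputs.econ.wtp_threshold
    rows = []
    for draw in range(n_sims):
        drawn = sample_draw(inputs, seed, draw)
        if cohort is None:
            sized = size_eligible_cohort(drawn.population, drawn.tkr_rate)
        else:
            sized = CohortSpec(n_eligible=dict(base_cohort.n_eligible))
        sampled_cohort = allocate_baseline_states(
            sized, {k: drawn.overall_baseline_props(k) for k in sized.n_eligible}
        )
        res = run_base_case(drawn, sampled_cohort)
        pp = res.per_person()
        rows.append(
            {
                "draw": draw,
                "delta_cost": pp["delta_cost"],
                "delta_qalys": pp["delta_qalys"],
                "inmb": pp["inmb"],
            }
        )
    draws = pd.DataFrame(rows)
    inmb = draws["inmb"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    de = draws["delta_qalys"].to_numpy()
    quadrants = {
        "higher_cost_higher_qaly": float(np.mean((dc > 0) & (de > 0))),
        "higher_cost_lower_qaly": float(np.mean((dc > 0) & (de <= 0))),
        "lower_cost_lower_qaly": float(np.mean((dc <= 0) & (de <= 0))),
        "lower_cost_higher_qaly": float(np.mean((dc <= 0) & (de > 0))),
    }
    result = PSAResult(
        draws=draws,
        seed=seed,
        wtp=wtp,
        mean_inmb=float(inmb.mean()),
        ci_inmb=(
            float(np.percentile(inmb, 2.5)),
            float(np.percentile(inmb, 97.5)),
        ),
        quadrant_fractions=quadrants,
    )
    result.ceac = ceac(result, thresholds)
    return result


def ceac(
    psa: PSAResult | pd.DataFrame, thresholds: np.ndarray | None = None, wtp: float | None = None
) -> pd.DataFrame:
    """Fraction of draws cost-effective across a willingness-to-pay grid."""
    if isinstance(psa, PSAResult):
        draws = psa.draws
        base_wtp = psa.wtp
    else:
        draws = psa
        if wtp is None:
            raise ValueError("wtp must be given when passing raw draws")
        base_wtp = wtp
    if thresholds is None:
        thresholds = np.linspace(0.0, 2.0 * base_wtp, 101)
    dc = draws["delta_cost"].to_numpy()
    de = draws["delta_qalys"].to_numpy()
    frac = [(float(np.mean(lam * de - dc > 0.0))) for lam in thresholds]
    return pd.DataFrame({"threshold": thresholds, "fraction_cost_effective": frac})
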