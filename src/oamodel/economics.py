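"""Discounted costs, QALYs and decision metrics.

Conventions (documented in docs/methods.md):

* discounting: cycle-1 flows undiscounted, factor ``(1+r)^-(t-1)``
  thereafter;
* utilities and any continuous cost stream accrue on the half-cycle
  (trapezoidal) corrected occupancy; per-event flows (procedure costs,
  the one-off revision disutility) are charged at full value in the
  cycle of the event;
* the program cost is a one-off charged to the whole exercise-arm cohort
  at the start of cycle 1;
* the incremental net monetary benefit is
  ``INMB = lambda * dQALY - dCost`` with both increments per person and
  the intervention (exercise) minus the comparator (usual care);
* the ICER is suppressed when both increments are negative (south-west
  quadrant), where its sign is uninterpretable; the INMB is the decision
  metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortSpec
from .engine import EXERCISE, USUAL_CARE, Trajectory, baseline_utilities, run_arm, state_utilities
from .inputs import Key, ModelInputs


def discount_factor(rate: float, cycle: int) -> float:
    """Discount factor for a 1-based cycle; cycle 1 is undiscounted."""
    if cycle < 1:
        raise ValueError("cycle is 1-based")
    return float((1.0 + rate) ** (-(cycle - 1)))


def convert_currency(amount_aud: float, rate: float) -> float:
    """A$ to US$ at ``rate`` USD per A$; rounding only at render time."""
    if rate <= 0:
        raise ValueError("currency rate must be positive")
    return amount_aud * rate


@dataclass
class ArmResult:
    """Discounted per-cycle streams for one arm, summed over strata."""

    arm: str
    n0: float  # initial cohort size (persons)
    cost: np.ndarray  # discounted A$ per cycle
    qalys: np.ndarray
    life_years: np.ndarray
    primaries: np.ndarray  # undiscounted event counts per cycle
    revisions: np.ndarray
    deaths: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.cost.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.qalys.sum())

    @property
    def total_life_years(self) -> float:
        return float(self.life_years.sum())

    @property
    def total_primaries(self) -> float:
        return float(self.primaries.sum())

    @property
    def total_revisions(self) -> float:
        return float(self.revisions.sum())


def _pad_add(total: np.ndarray | None, part: np.ndarray) -> np.ndarray:
    if total is None:
        return part.copy()
    if len(part) > len(total):
        total = np.pad(total, (0, len(part) - len(total)))
    elif len(total) > len(part):
        part = np.pad(part, (0, len(total) - len(part)))
    return total + part


def accumulate(
    trajectories: dict[Key, Trajectory],
    inputs: ModelInputs,
    arm: str,
    hospital: str | None = None,
) -> ArmResult:
    """Turn per-stratum trajectories into discounted cost/QALY streams.

    ``hospital`` selects hospital-type-specific procedure costs for the
    hospital subgroup analyses; the default uses the weighted means.
    """
    c_primary, c_revision = inputs.effective_costs(hospital)
    c_program = inputs.costs.nonsurgical_program
    du_event = inputs.settings.revision_disutility.event
    other_delta = inputs.costs.other_annual_cost_delta
    other_years = inputs.costs.other_annual_cost_years
    r = inputs.econ.discount_rate

    cost = qalys = lys = prim = rev = dth = None
    n0 = 0.0
    if not trajectories:  # empty subgroup: legitimate n = 0 result
        zero = np.zeros(1)
        return ArmResult(arm, 0.0, zero, zero.copy(), zero.copy(), zero.copy(), zero.copy(), zero.copy())
    for key, traj in trajectories.items():
        n_cycles = traj.n_cycles
        disc = np.array([discount_factor(r, t) for t in range(1, n_cycles + 1)])
        u_state = state_utilities(inputs, key)
        u_init = baseline_utilities(inputs, key)
        occ = traj.occupancy
        # trapezoid: start-of-cycle utility uses the pre-intervention
        # (baseline) utilities in cycle 1
        start_u = occ[:-1] @ u_state
        start_u[0] = occ[0] @ u_init
        end_u = occ[1:] @ u_state
        q_stream = disc * 0.5 * (start_u + end_u)
        q_stream -= disc * du_event * traj.revisions

        alive = traj.alive()
        alive_mid = 0.5 * (alive[:-1] + alive[1:])
        ly_stream = disc * alive_mid

        c_stream = disc * (c_primary * traj.primaries + c_revision * traj.revisions)
        if arm == EXERCISE:
            c_stream[0] += c_program * alive[0]
        if other_delta != 0.0:
            w = min(other_years, n_cycles)
            c_stream[:w] += disc[:w] * other_delta * alive_mid[:w]

        n0 += float(alive[0])
        cost = _pad_add(cost, c_stream)
        qalys = _pad_add(qalys, q_stream)
        lys = _pad_add(lys, ly_stream)
        prim = _pad_add(prim, traj.primaries)
        rev = _pad_add(rev, traj.revisions)
        dth = _pad_add(dth, traj.deaths)

    return ArmResult(arm, n0, cost, qalys, lys, prim, rev, dth)


def evaluate_arm(
    arm: str,
    cohort: CohortSpec,
    inputs: ModelInputs,
    hospital: str | None = None,
    horizon: int | None = None,
) -> ArmResult:
    """Run the engine for one arm and accumulate its economic streams."""
    traj = run_arm(arm, cohort, inputs, horizon=horizon)
    return accumulate(traj, inputs, arm, hospital=hospital)


def compute_inmb(delta_cost: float, delta_qalys: float, wtp: float) -> float:
    """Incremental net monetary benefit at willingness-to-pay ``wtp``."""
    if wtp <= 0:
        raise ValueError("willingness-to-pay threshold must be positive")
    return wtp * delta_qalys - delta_cost


@dataclass
class EconResult:
    """Cohort-level economic comparison: exercise arm minus usual care."""

    name: str
    n: float
    exercise: ArmResult
    usual_care: ArmResult
    wtp: float
    currency_rate: float

    @property
    def delta_cost(self) -> float:
        return self.exercise.total_cost - self.usual_care.total_cost

    @property
    def delta_qalys(self) -> float:
        return self.exercise.total_qalys - self.usual_care.total_qalys

    @property
    def delta_life_years(self) -> float:
        return self.exercise.total_life_years - self.usual_care.total_life_years

    @property
    def inmb_per_person(self) -> float:
        if self.n == 0:
            return 0.0
        return compute_inmb(self.delta_cost / self.n, self.delta_qalys / self.n, self.wtp)

    @property
    def icer(self) -> float | None:
        """Cost per QALY; ``None`` in the south-west quadrant (both negative)."""
        if self.n == 0 or self.delta_qalys == 0:
            return None
        if self.delta_cost < 0 and self.delta_qalys < 0:
            return None
        return self.delta_cost / self.delta_qalys

    @property
    def fewer_primaries(self) -> float:
        return self.usual_care.total_primaries - self.exercise.total_primaries

    @property
    def fewer_revisions(self) -> float:
        return self.usual_care.total_revisions - self.exercise.total_revisions

    @property
    def tkr_avoidance_fraction(self) -> float:
        if self.usual_care.total_primaries == 0:
            return 0.0
        return self.fewer_primaries / self.usual_care.total_primaries

    def per_person(self) -> dict[str, float]:
        n = self.n if self.n else 1.0
        return {
            "cost_exercise": self.exercise.total_cost / n,
            "cost_usual_care": self.usual_care.total_cost / n,
            "qalys_exercise": self.exercise.total_qalys / n,
            "qalys_usual_care": self.usual_care.total_qalys / n,
            "delta_cost": self.delta_cost / n,
            "delta_qalys": self.delta_qalys / n,
            "inmb": self.inmb_per_person,
        }

    def cohort_total(self) -> dict[str, float]:
        return {
            "cost_exercise": self.exercise.total_cost,
            "cost_usual_care": self.usual_care.total_cost,
            "qalys_exercise": self.exercise.total_qalys,
            "qalys_usual_care": self.usual_care.total_qalys,
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "inmb": self.inmb_per_person * self.n,
        }

    def to_row(self) -> dict[str, float | str | None]:
        pp = self.per_person()
        return {
            "name": self.name,
            "n": self.n,
            "cost_exercise_aud": self.exercise.total_cost,
            "cost_usual_care_aud": self.usual_care.total_cost,
            "delta_cost_aud": self.delta_cost,
            "delta_cost_usd": convert_currency(self.delta_cost, self.currency_rate),
            "qalys_exercise": self.exercise.total_qalys,
            "qalys_usual_care": self.usual_care.total_qalys,
            "delta_qalys": self.delta_qalys,
            "delta_cost_per_person_aud": pp["delta_cost"],
            "delta_qalys_per_person": pp["delta_qalys"],
            "inmb_per_person_aud": self.inmb_per_person,
            "inmb_per_person_usd": convert_currency(
                self.inmb_per_person, self.currency_rate
            ),
            "icer_aud_per_qaly": self.icer,
        }


def run_base_case(
    inputs: ModelInputs,
    cohort: CohortSpec,
    name: str = "base_case",
    hospital: str | None = None,
) -> EconResult:
    """Run both arms on a cohort and return the comparison."""
    ex = evaluate_arm(EXERCISE, cohort, inputs, hospital=hospital)
    uc = evaluate_arm(USUAL_CARE, cohort, inputs, hospital=hospital)
    return EconResult(
        name=name,
        n=cohort.total_n,
        exercise=ex,
        usual_care=uc,
        wtp=inputs.econ.wtp_threshold,
        currency_rate=inputs.econ.currency_rate,
    )


def horizon_sweep(result: EconResult) -> pd.DataFrame:
    """INMB as a function of the truncation horizon ``h`` (in cycles).

    Returns one row per horizon with the cumulative discounted increments
    and the INMB of the model truncated there.
    """
    n = result.n if result.n else 1.0
    h_max = max(len(result.exercise.cost), len(result.usual_care.cost))

    def cum(arr: np.ndarray) -> np.ndarray:
        return np.cumsum(np.pad(arr, (0, h_max - len(arr))))

    dc = (cum(result.exercise.cost) - cum(result.usual_care.cost)) / n
    de = (cum(result.exercise.qalys) - cum(result.usual_care.qalys)) / n
    inmb = result.wtp * de - dc
    return pd.DataFrame(
        {
            "horizon": np.arange(1, h_max + 1),
            "delta_cost_per_person": dc,
            "delta_qalys_per_person": de,
            "inmb_per_person": inmb,
        }
    )


def crossover_horizon(sweep: pd.DataFrame) -> int | None:
    """Largest horizon (years) at which the program is still cost-effective."""
    ok = sweep.loc[sweep["inmb_per_person"] >= 0, "horizon"]
    return None if ok.empty else int(ok.max())
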