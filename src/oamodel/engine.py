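"""Annual-cycle semi-Markov cohort engine.

Both arms run on the expanded state space of :mod:`oamodel.states`.

Event order within a cycle is fixed: death first (all-cause probability,
multiplied by the excess ratio for post-surgical states, capped at 1),
then surgery among survivors.  In the usual-care arm the whole surviving
cohort undergoes the primary replacement in cycle 1; in the exercise arm
a fraction converts to surgery each year (``p_tkr_year1`` in cycle 1,
``p_tkr_subsequent`` afterwards).  Converters receive the post-operative
pain-state transition from their pain state at conversion and enter the
first post-primary tunnel; cycle-1 non-converters receive the 12-month
exercise-program transition once, after which their pain state is held.
Post-primary occupants face the year-since-primary revision hazard;
revision moves them to the revised tunnel (pain state unchanged).
Everyone still alive at ``max_age`` dies at the end of that cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import CohortSpec
from .inputs import Key, ModelInputs
from .states import (
    DEAD,
    K_MAX,
    N_PAIN,
    N_STATES,
    PP0,
    PRE0,
    REV0,
    Stratum,
    idx_pp,
    idx_pre,
    idx_rev,
)

log = logging.getLogger(__name__)

USUAL_CARE = "usual_care"
EXERCISE = "exercise"
ARM_NAMES = (USUAL_CARE, EXERCISE)


@dataclass
class CycleOperator:
    """One-cycle transition matrix plus per-state event probabilities."""

    matrix: np.ndarray  # (N_STATES, N_STATES), row stochastic
    primary_rate: np.ndarray  # P(primary TKR this cycle | in state at start)
    revision_rate: np.ndarray
    death_rate: np.ndarray


@dataclass
class Trajectory:
    """Occupancy and event counts for one stratum and arm."""

    stratum: Stratum
    arm: str
    occupancy: np.ndarray  # (n_cycles + 1, N_STATES); row 0 = baseline
    primaries: np.ndarray  # events per cycle, length n_cycles
    revisions: np.ndarray
    deaths: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive(self) -> np.ndarray:
        """Alive mass at each cycle boundary."""
        return self.occupancy.sum(axis=1) - self.occupancy[:, DEAD]


def build_cycle_matrix(
    stratum: Stratum, arm: str, cycle: int, inputs: ModelInputs
) -> CycleOperator:
    """Assemble the one-cycle operator for a stratum/arm at a given cycle.

    ``cycle`` is 1-based; the attained age during the cycle is
    ``start_age + cycle - 1``.
    """
    if arm not in ARM_NAMES:
        raise ValueError(f"unknown arm {arm!r}")
    age = stratum.start_age + cycle - 1
    q = inputs.q(age, stratum.sex)
    ratios = inputs.excess_ratio_by_year()
    force_death = age >= inputs.econ.max_age

    q_post = q * ratios
    if np.any(q_post > 1.0):
        log.warning(
            "capping q*excess_ratio > 1 at age %d (%s)", age, stratum.sex
        )
        q_post = np.minimum(q_post, 1.0)
    if force_death:
        q = 1.0
        q_post = np.ones_like(q_post)

    if arm == USUAL_CARE:
        uptake = 1.0 if cycle == 1 else 0.0
    else:
        uptake = (
            inputs.uptake.p_tkr_year1 if cycle == 1 else inputs.uptake.p_tkr_subsequent
        )

    P_tkr = inputs.transitions[("post_tkr", stratum.key)]
    P_ex = inputs.transitions[("exercise", stratum.key)]
    rev_p = inputs.revision[stratum.key]

    M = np.zeros((N_STATES, N_STATES))
    primary_rate = np.zeros(N_STATES)
    revision_rate = np.zeros(N_STATES)
    death_rate = np.zeros(N_STATES)

    # pre-surgery (exercise program) states
    for o in range(N_PAIN):
        for c in range(N_PAIN):
            i = idx_pre(o, c)
            s = 1.0 - q
            M[i, DEAD] = q
            death_rate[i] = q
            if s == 0.0:
                continue
            conv = s * uptake
            primary_rate[i] = conv
            for p in range(N_PAIN):
                M[i, idx_pp(1, p)] += conv * P_tkr[c, p]
            stay = s - conv
            if stay > 0.0:
                if cycle == 1 and arm == EXERCISE:
                    for c2 in range(N_PAIN):
                        M[i, idx_pre(o, c2)] += stay * P_ex[c, c2]
                else:
                    M[i, i] += stay

    # post-primary tunnels
    for k in range(1, K_MAX + 1):
        k2 = min(k + 1, K_MAX)
        d = q_post[k - 1]
        s = 1.0 - d
        r = rev_p[k - 1]
        for p in range(N_PAIN):
            i = idx_pp(k, p)
            M[i, DEAD] = d
            death_rate[i] = d
            M[i, idx_rev(k2, p)] += s * r
            M[i, idx_pp(k2, p)] += s * (1.0 - r)
            revision_rate[i] = s * r
            j = idx_rev(k, p)
            M[j, DEAD] = d
            death_rate[j] = d
            M[j, idx_rev(k2, p)] += s

    M[DEAD, DEAD] = 1.0
    return CycleOperator(M, primary_rate, revision_rate, death_rate)


def initial_occupancy(allocation: np.ndarray) -> np.ndarray:
    """Baseline occupancy: everyone pre-surgical, current = origin pain state."""
    occ = np.zeros(N_STATES)
    for o in range(N_PAIN):
        occ[idx_pre(o, o)] = allocation[o]
    return occ


def run_arm(
    arm: str,
    cohort: CohortSpec,
    inputs: ModelInputs,
    horizon: int | None = None,
) -> dict[Key, Trajectory]:
    """Run one arm for every stratum in the cohort.

    The default horizon is lifetime: ``max_age - start_age + 1`` cycles per
    stratum (everyone alive at ``max_age`` dies in that final cycle).  An
    explicit longer horizon is truncated per stratum with a log entry.
    """
    out: dict[Key, Trajectory] = {}
    for key, allocation in cohort.baseline_allocation.items():
        stratum = inputs.stratum(key)
        lifetime = inputs.econ.max_age - stratum.start_age + 1
        n_cycles = lifetime if horizon is None else min(horizon, lifetime)
        if horizon is not None and horizon > lifetime:
            log.info(
                "horizon %d truncated to lifetime %d for stratum %s",
                horizon,
                lifetime,
                key,
            )
        occ = np.zeros((n_cycles + 1, N_STATES))
        occ[0] = initial_occupancy(allocation)
        primaries = np.zeros(n_cycles)
        revisions = np.zeros(n_cycles)
        deaths = np.zeros(n_cycles)
        for t in range(1, n_cycles + 1):
            op = build_cycle_matrix(stratum, arm, t, inputs)
            primaries[t - 1] = occ[t - 1] @ op.primary_rate
            revisions[t - 1] = occ[t - 1] @ op.revision_rate
            deaths[t - 1] = occ[t - 1] @ op.death_rate
            occ[t] = occ[t - 1] @ op.matrix
        out[key] = Trajectory(stratum, arm, occ, primaries, revisions, deaths)
    return out


def half_cycle_occupancy(trajectory: Trajectory) -> np.ndarray:
    """Trapezoidal effective occupancy: mean of cycle-start and cycle-end."""
    occ = trajectory.occupancy
    return 0.5 * (occ[:-1] + occ[1:])


# ---------------------------------------------------------------------------
# utility vectors over the expanded space
# ---------------------------------------------------------------------------


def state_utilities(inputs: ModelInputs, key: Key) -> np.ndarray:
    """Utility of each expanded state *after* cycle-1 transitions.

    Pre-surgical: baseline utility of the origin state plus the
    incremental utility of the origin -> current program transition.
    Post-primary: post-operative state utility.  Post-revision: the same
    minus the chronic revision disutility.  Dead: 0.
    """
    u_base = inputs.utilities[(key, "baseline")]
    u_post = inputs.utilities[(key, "post_tkr")]
    chronic = inputs.settings.revision_disutility.chronic
    inc = inputs.incremental_utility
    u = np.zeros(N_STATES)
    for o in range(N_PAIN):
        for c in range(N_PAIN):
            u[idx_pre(o, c)] = u_base[o] + inc[o, c]
    for k in range(1, K_MAX + 1):
        for p in range(N_PAIN):
            u[idx_pp(k, p)] = u_post[p]
            u[idx_rev(k, p)] = u_post[p] - chronic
    u[DEAD] = 0.0
    return u


def baseline_utilities(inputs: ModelInputs, key: Key) -> np.ndarray:
    """Utility vector at time zero, before any intervention has acted."""
    u = state_utilities(inputs, key).copy()
    u_base = inputs.utilities[(key, "baseline")]
    for o in range(N_PAIN):
        for c in range(N_PAIN):
            u[idx_pre(o, c)] = u_base[o]
    return u
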