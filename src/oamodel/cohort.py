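"""Construction of the hypothetical national cohort.

The cohort is everyone who would have undergone a primary knee
replacement in the index year: age/sex-specific procedure rates applied
to population counts.  Persons are carried as continuous masses
throughout; rounding happens only when reports are rendered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inputs import Key, ModelInputs


@dataclass
class CohortSpec:
    """Eligible persons per stratum and their baseline pain-state split."""

    n_eligible: dict[Key, float]
    baseline_allocation: dict[Key, np.ndarray] = field(default_factory=dict)

    @property
    def total_n(self) -> float:
        return float(sum(self.n_eligible.values()))

    def restrict_to_state(self, state: int) -> "CohortSpec":
        """Sub-cohort of people starting in one baseline pain state."""
        alloc = {}
        n = {}
        for key, a in self.baseline_allocation.items():
            sub = np.zeros_like(a)
            sub[state] = a[state]
            alloc[key] = sub
            n[key] = float(sub.sum())
        return CohortSpec(n_eligible=n, baseline_allocation=alloc)

    def restrict_to_strata(self, keys: list[Key]) -> "CohortSpec":
        keys = set(keys)
        return CohortSpec(
            n_eligible={k: v for k, v in self.n_eligible.items() if k in keys},
            baseline_allocation={
                k: v.copy() for k, v in self.baseline_allocation.items() if k in keys
            },
        )

    def scaled(self, factor: float) -> "CohortSpec":
        return CohortSpec(
            n_eligible={k: v * factor for k, v in self.n_eligible.items()},
            baseline_allocation={
                k: v * factor for k, v in self.baseline_allocation.items()
            },
        )


def size_eligible_cohort(
    population: dict[Key, float], tkr_rate: dict[Key, float]
) -> CohortSpec:
    """Eligible persons = population x annual procedure rate, per stratum."""
    n = {}
    for key, pop in population.items():
        rate = tkr_rate[key]
        if pop < 0 or rate < 0:
            raise ValueError(f"negative population or rate for stratum {key}")
        n[key] = pop * rate
    return CohortSpec(n_eligible=n)


def allocate_baseline_states(
    cohort: CohortSpec, baseline_proportions: dict[Key, np.ndarray]
) -> CohortSpec:
    """Fill the baseline pain-state allocation from per-stratum proportions."""
    alloc = {}
    for key, n in cohort.n_eligible.items():
        p = np.asarray(baseline_proportions[key], dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"baseline proportions for stratum {key} do not sum to 1: {p.tolist()}"
            )
        alloc[key] = n * p
    return CohortSpec(n_eligible=dict(cohort.n_eligible), baseline_allocation=alloc)


def build_cohort(
    inputs: ModelInputs, hospital: str | None = None
) -> CohortSpec:
    """Cohort from a bundle; ``hospital`` restricts to one hospital type."""
    cohort = size_eligible_cohort(inputs.population, inputs.tkr_rate)
    if hospital is None:
        props = {s.key: inputs.overall_baseline_props(s.key) for s in inputs.strata}
    else:
        share = inputs.hospital_share(hospital)
        cohort = cohort.scaled(share)
        props = {s.key: inputs.baseline_props[(s.key, hospital)] for s in inputs.strata}
    return allocate_baseline_states(cohort, props)
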