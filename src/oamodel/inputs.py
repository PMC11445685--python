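"""The model input bundle: schema, loading, validation and serialisation.

A bundle is a directory of plain CSV tables plus one ``settings.json``:

========================  =====================================================
file                      columns
========================  =====================================================
population.csv            age_band, sex, population, tkr_rate
baseline_proportions.csv  age_band, sex, hospital, n_effective,
                          no_mild, moderate, severe_extreme
mortality.csv             age, sex, q
excess_mortality.csv      years_lo, years_hi, ratio   (years_hi empty = open)
transitions_tkr.csv       age_band, sex, from_state, n_effective,
transitions_exercise.csv  no_mild, moderate, severe_extreme
revision.csv              age_band, sex, year, p_revision
utilities.csv             age_band, sex, context, state, utility
incremental_utilities.csv from_state, to_state, delta
settings.json             EconSettings / CostParams / UptakeParams /
                          revision disutilities / hospital mix / PSA defaults
========================  =====================================================

Probabilities are decimals, money is 2022 Australian dollars.  Transition
rows are conditional on surviving the cycle, so each row sums to one over
the three alive destinations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .distributions import DistributionSpec
from .states import (
    AGE_BANDS,
    K_MAX,
    PAIN_LABELS,
    SEXES,
    Stratum,
    band_midpoint_age,
)

ARMS = ("post_tkr", "exercise")
CONTEXTS = ("baseline", "post_tkr")
HOSPITALS = ("public", "private")

BUNDLE_FILES = (
    "population.csv",
    "baseline_proportions.csv",
    "mortality.csv",
    "excess_mortality.csv",
    "transitions_tkr.csv",
    "transitions_exercise.csv",
    "revision.csv",
    "utilities.csv",
    "incremental_utilities.csv",
    "settings.json",
)

ROW_SUM_TOL = 1e-9


class BundleError(Exception):
    """Base class for bundle problems."""


class BundleLoadError(BundleError):
    """A file or column is missing or unreadable."""


class BundleValidationError(BundleError):
    """An invariant is violated; the message names the offending cell."""


# ---------------------------------------------------------------------------
# settings.json models
# ---------------------------------------------------------------------------


class EconSettings(BaseModel):
    """Economic evaluation settings (annual cycles, health-system perspective)."""

    discount_rate: float = 0.05
    wtp_threshold: float = 28033.0  # A$ per QALY gained
    currency_rate: float = 0.6947  # USD per A$
    max_age: int = 100
    cycle_length: int = 1
    start_age_offset: int = 5

    @model_validator(mode="after")
    def _check(self) -> "EconSettings":
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError(f"discount_rate {self.discount_rate} outside [0, 1)")
        if self.wtp_threshold <= 0 or self.currency_rate <= 0:
            raise ValueError("wtp_threshold and currency_rate must be positive")
        if self.max_age <= 45:
            raise ValueError("max_age must exceed the youngest start age")
        return self


class CostParams(BaseModel):
    """Per-event costs in 2022 A$.

    ``primary_tkr`` / ``revision_tkr`` are the cohort-weighted means; when
    omitted they are derived from the public/private components and the
    hospital mix.
    """

    primary_tkr_public: float = 20955.0
    primary_tkr_private: float = 25435.0
    revision_tkr_public: float = 43233.0
    revision_tkr_private: float = 43078.0
    primary_tkr: float | None = None
    revision_tkr: float | None = None
    nonsurgical_program: float = 1500.0
    nonsurgical_low: float = 750.0
    nonsurgical_high: float = 3000.0
    surgical_se_frac: float = 0.15
    other_annual_cost_delta: float = 0.0
    other_annual_cost_years: int = 5

    @model_validator(mode="after")
    def _check(self) -> "CostParams":
        for name in (
            "primary_tkr_public",
            "primary_tkr_private",
            "revision_tkr_public",
            "revision_tkr_private",
            "nonsurgical_program",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"cost {name} must be nonnegative")
        for name in ("primary_tkr", "revision_tkr"):
            w = getattr(self, name)
            if w is None:
                continue
            lo = min(getattr(self, f"{name}_public"), getattr(self, f"{name}_private"))
            hi = max(getattr(self, f"{name}_public"), getattr(self, f"{name}_private"))
            if not lo <= w <= hi:
                raise ValueError(
                    f"weighted {name} {w} outside public/private range [{lo}, {hi}]"
                )
        return self


class UptakeParams(BaseModel):
    """Annual probability of converting to surgery after the program."""

    p_tkr_year1: float = 0.26
    p_tkr_year1_ci: tuple[float, float] = (0.14, 0.38)
    p_tkr_subsequent: float = 0.08
    p_tkr_subsequent_ci: tuple[float, float] = (0.03, 0.21)

    @model_validator(mode="after")
    def _check(self) -> "UptakeParams":
        for mean, (lo, hi), name in (
            (self.p_tkr_year1, self.p_tkr_year1_ci, "p_tkr_year1"),
            (self.p_tkr_subsequent, self.p_tkr_subsequent_ci, "p_tkr_subsequent"),
        ):
            if not 0.0 < mean < 1.0:
                raise ValueError(f"{name} {mean} outside (0, 1)")
            if not lo <= mean <= hi:
                raise ValueError(f"{name} CI ({lo}, {hi}) does not bracket {mean}")
        return self


class RevisionDisutility(BaseModel):
    """Quality-of-life decrements around a revision procedure."""

    event: float = 0.28  # applied once, in the cycle of the revision
    chronic: float = 0.10  # applied every cycle lived in the revised state
    se_frac: float = 0.25

    @model_validator(mode="after")
    def _check(self) -> "RevisionDisutility":
        if self.event < 0 or self.chronic < 0:
            raise ValueError("disutilities must be nonnegative")
        return self


class PsaDefaults(BaseModel):
    """Default dispersion parameters where only a family is reported."""

    excess_ratio_sdlog: float = 0.1
    mortality_sdlog: float = 0.05
    revision_prob_n_effective: float = 1000.0
    exercise_utility_se: float = 0.025


class Settings(BaseModel):
    econ: EconSettings = Field(default_factory=EconSettings)
    costs: CostParams = Field(default_factory=CostParams)
    uptake: UptakeParams = Field(default_factory=UptakeParams)
    revision_disutility: RevisionDisutility = Field(default_factory=RevisionDisutility)
    hospital_mix_public: float = 0.269
    psa: PsaDefaults = Field(default_factory=PsaDefaults)

    @model_validator(mode="after")
    def _check(self) -> "Settings":
        if not 0.0 <= self.hospital_mix_public <= 1.0:
            raise ValueError("hospital_mix_public must lie in [0, 1]")
        return self


# ---------------------------------------------------------------------------
# the validated in-memory bundle
# ---------------------------------------------------------------------------

Key = tuple[str, str]  # (age_band, sex)


@dataclass
class ModelInputs:
    """Fully validated input bundle for one model run."""

    settings: Settings
    strata: list[Stratum]
    population: dict[Key, float]
    tkr_rate: dict[Key, float]
    # baseline pain-state proportions and their Dirichlet pseudo-counts,
    # per stratum and hospital type
    baseline_props: dict[tuple[Key, str], np.ndarray]
    baseline_n_eff: dict[tuple[Key, str], float]
    mortality_age_min: int
    mortality_q: dict[str, np.ndarray]  # sex -> q by single year of age
    excess_intervals: list[tuple[int, int | None, float]]
    transitions: dict[tuple[str, Key], np.ndarray]  # (arm, key) -> 3x3
    transition_n_eff: dict[tuple[str, Key], np.ndarray]  # per from-state row
    revision: dict[Key, np.ndarray]  # annual revision prob, years 1..K_MAX
    utilities: dict[tuple[Key, str], np.ndarray]  # (key, context) -> u[pain]
    incremental_utility: np.ndarray  # [from, to] exercise-arm increment
    distributions: list[DistributionSpec] = field(default_factory=list)

    # -- convenience accessors ---------------------------------------------

    @property
    def econ(self) -> EconSettings:
        return self.settings.econ

    @property
    def costs(self) -> CostParams:
        return self.settings.costs

    @property
    def uptake(self) -> UptakeParams:
        return self.settings.uptake

    def stratum(self, key: Key) -> Stratum:
        for s in self.strata:
            if s.key == key:
                return s
        raise KeyError(key)

    def hospital_types(self) -> tuple[str, ...]:
        hs = sorted({h for (_, h) in self.baseline_props})
        return tuple(hs)

    def hospital_share(self, hospital: str) -> float:
        mix = self.settings.hospital_mix_public
        if hospital == "public":
            return mix
        if hospital == "private":
            return 1.0 - mix
        return 1.0

    def overall_baseline_props(self, key: Key) -> np.ndarray:
        """Hospital-mix-weighted baseline pain-state proportions."""
        total = np.zeros(3)
        weight = 0.0
        for h in self.hospital_types():
            share = self.hospital_share(h)
            total += share * self.baseline_props[(key, h)]
            weight += share
        return total / weight

    def effective_costs(self, hospital: str | None = None) -> tuple[float, float]:
        """(primary, revision) per-event cost, weighted or hospital-specific."""
        c = self.costs
        if hospital == "public":
            return c.primary_tkr_public, c.revision_tkr_public
        if hospital == "private":
            return c.primary_tkr_private, c.revision_tkr_private
        mix = self.settings.hospital_mix_public
        primary = (
            c.primary_tkr
            if c.primary_tkr is not None
            else mix * c.primary_tkr_public + (1 - mix) * c.primary_tkr_private
        )
        revision = (
            c.revision_tkr
            if c.revision_tkr is not None
            else mix * c.revision_tkr_public + (1 - mix) * c.revision_tkr_private
        )
        return primary, revision

    def q(self, age: int, sex: str) -> float:
        """Annual all-cause death probability, clamped to the table range."""
        arr = self.mortality_q[sex]
        i = int(np.clip(age - self.mortality_age_min, 0, len(arr) - 1))
        return float(arr[i])

    def excess_ratio_by_year(self) -> np.ndarray:
        """Excess-mortality ratio for each year since primary, 1..K_MAX."""
        out = np.ones(K_MAX)
        for lo, hi, ratio in self.excess_intervals:
            top = K_MAX if hi is None else min(hi, K_MAX)
            if lo <= K_MAX:
                out[lo - 1 : top] = ratio
        return out

    def clone(self) -> "ModelInputs":
        """Deep, independent copy (used per PSA draw / DSA bound)."""
        return ModelInputs(
            settings=self.settings.model_copy(deep=True),
            strata=list(self.strata),
            population=dict(self.population),
            tkr_rate=dict(self.tkr_rate),
            baseline_props={k: v.copy() for k, v in self.baseline_props.items()},
            baseline_n_eff=dict(self.baseline_n_eff),
            mortality_age_min=self.mortality_age_min,
            mortality_q={k: v.copy() for k, v in self.mortality_q.items()},
            excess_intervals=list(self.excess_intervals),
            transitions={k: v.copy() for k, v in self.transitions.items()},
            transition_n_eff={k: v.copy() for k, v in self.transition_n_eff.items()},
            revision={k: v.copy() for k, v in self.revision.items()},
            utilities={k: v.copy() for k, v in self.utilities.items()},
            incremental_utility=self.incremental_utility.copy(),
            distributions=list(self.distributions),
        )

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        keys = [s.key for s in self.strata]
        if len(set(keys)) != len(keys) or not keys:
            raise BundleValidationError("strata must be nonempty and unique")
        for table_name, table_keys in (
            ("population.csv", set(self.population)),
            ("revision.csv", set(self.revision)),
        ):
            if table_keys != set(keys):
                raise BundleValidationError(
                    f"{table_name}: strata {sorted(table_keys)} do not match "
                    f"population strata {sorted(keys)}"
                )
        hs = self.hospital_types()
        for key in keys:
            for h in hs:
                if (key, h) not in self.baseline_props:
                    raise BundleValidationError(
                        f"baseline_proportions.csv: missing stratum {key} hospital {h}"
                    )
                p = self.baseline_props[(key, h)]
                if np.any(p < 0) or abs(p.sum() - 1.0) > ROW_SUM_TOL:
                    raise BundleValidationError(
                        f"baseline_proportions.csv: stratum {key} hospital {h} "
                        f"proportions {p.tolist()} do not sum to 1"
                    )
            for arm in ARMS:
                P = self.transitions.get((arm, key))
                if P is None:
                    raise BundleValidationError(
                        f"transitions ({arm}): missing stratum {key}"
                    )
                for i, row in enumerate(P):
                    if np.any(row < 0) or np.any(row > 1) or abs(row.sum() - 1.0) > ROW_SUM_TOL:
                        raise BundleValidationError(
                            f"transitions ({arm}): stratum {key} row "
                            f"{PAIN_LABELS[i]} sums to {row.sum():.12f}, expected 1"
                        )
            r = self.revision[key]
            if len(r) != K_MAX or np.any(r < 0) or np.any(r > 1):
                raise BundleValidationError(
                    f"revision.csv: stratum {key} needs {K_MAX} probabilities in [0, 1]"
                )
            for ctx in CONTEXTS:
                u = self.utilities.get((key, ctx))
                if u is None:
                    raise BundleValidationError(
                        f"utilities.csv: missing stratum {key} context {ctx}"
                    )
                if np.any(u > 1.0) or np.any(u < -1.0):
                    raise BundleValidationError(
                        f"utilities.csv: stratum {key} context {ctx} outside [-1, 1]"
                    )
            if self.population[key] < 0 or self.tkr_rate[key] < 0:
                raise BundleValidationError(
                    f"population.csv: stratum {key} has negative population or rate"
                )
        for sex in SEXES:
            qs = self.mortality_q.get(sex)
            if qs is None or len(qs) == 0:
                raise BundleValidationError(f"mortality.csv: no rows for sex {sex}")
            if np.any(qs < 0) or np.any(qs >= 1):
                raise BundleValidationError(f"mortality.csv: q outside [0, 1) for {sex}")
            if np.any(np.diff(qs) < -1e-12):
                age = self.mortality_age_min + int(np.argmax(np.diff(qs) < -1e-12)) + 1
                raise BundleValidationError(
                    f"mortality.csv: q decreases with age at {sex} age {age}"
                )
        for lo, hi, ratio in self.excess_intervals:
            if ratio <= 0:
                raise BundleValidationError(
                    f"excess_mortality.csv: nonpositive ratio in interval {lo}-{hi}"
                )
        if self.incremental_utility.shape != (3, 3):
            raise BundleValidationError("incremental_utilities.csv must be 3x3")
        max_age = self.econ.max_age
        for s in self.strata:
            if s.start_age >= max_age:
                raise BundleValidationError(
                    f"stratum {s.key} start_age {s.start_age} >= max_age {max_age}"
                )
        for spec in self.distributions:
            resolve_target(self, spec.target)  # raises if unresolvable


# ---------------------------------------------------------------------------
# target paths (used by DSA/PSA to perturb a loaded bundle in place)
# ---------------------------------------------------------------------------


def resolve_target(inputs: ModelInputs, path: str):
    """Return the current value of a dotted target path; raise if absent."""
    if not path:
        raise BundleValidationError("empty distribution target")
    head, _, rest = path.partition(".")
    if head == "settings":
        obj = inputs.settings
        for part in rest.split("."):
            if not hasattr(obj, part):
                raise BundleValidationError(f"unresolvable target {path!r}")
            obj = getattr(obj, part)
        return obj
    if head == "excess_ratio":
        i = int(rest)
        if not 0 <= i < len(inputs.excess_intervals):
            raise BundleValidationError(f"unresolvable target {path!r}")
        return inputs.excess_intervals[i][2]
    if head == "mortality_multiplier":
        return 1.0
    if head == "exercise_utility_shift":
        return 0.0
    raise BundleValidationError(f"unresolvable target {path!r}")


def set_target(inputs: ModelInputs, path: str, value: float) -> None:
    """Set a scalar target path on a (cloned) bundle."""
    head, _, rest = path.partition(".")
    if head == "settings":
        parts = rest.split(".")
        obj = inputs.settings
        for part in parts[:-1]:
            obj = getattr(obj, part)
        object.__setattr__(obj, parts[-1], value)
        return
    if head == "excess_ratio":
        i = int(rest)
        lo, hi, _ = inputs.excess_intervals[i]
        inputs.excess_intervals[i] = (lo, hi, float(value))
        return
    if head == "mortality_multiplier":
        for sex in inputs.mortality_q:
            inputs.mortality_q[sex] = np.clip(inputs.mortality_q[sex] * value, 0.0, 0.999999)
        return
    if head == "exercise_utility_shift":
        inputs.incremental_utility = inputs.incremental_utility + value
        return
    raise BundleValidationError(f"unresolvable target {path!r}")


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------


def _read_csv(path: Path, name: str, columns: list[str]) -> pd.DataFrame:
    f = path / name
    if not f.exists():
        raise BundleLoadError(f"missing bundle file {name}")
    df = pd.read_csv(f)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise BundleLoadError(f"{name}: missing columns {missing}")
    return df


def _state_index(label: str, file: str) -> int:
    if label not in PAIN_LABELS:
        raise BundleLoadError(f"{file}: unknown state label {label!r}")
    return PAIN_LABELS.index(label)


def load_input_bundle(path: str | Path) -> ModelInputs:
    """Read and validate a bundle directory into :class:`ModelInputs`."""
    path = Path(path)
    settings_file = path / "settings.json"
    if not settings_file.exists():
        raise BundleLoadError("missing bundle file settings.json")
    try:
        settings = Settings.model_validate(json.loads(settings_file.read_text()))
    except ValueError as exc:
        raise BundleValidationError(f"settings.json: {exc}") from exc

    pop = _read_csv(path, "population.csv", ["age_band", "sex", "population", "tkr_rate"])
    offset = settings.econ.start_age_offset
    strata, population, tkr_rate = [], {}, {}
    for _, row in pop.iterrows():
        s = Stratum(row["age_band"], row["sex"], band_midpoint_age(row["age_band"], offset))
        strata.append(s)
        population[s.key] = float(row["population"])
        tkr_rate[s.key] = float(row["tkr_rate"])

    bp = _read_csv(
        path,
        "baseline_proportions.csv",
        ["age_band", "sex", "hospital", "n_effective", *PAIN_LABELS],
    )
    baseline_props, baseline_n_eff = {}, {}
    for _, row in bp.iterrows():
        key = (row["age_band"], row["sex"])
        baseline_props[(key, row["hospital"])] = np.array(
            [float(row[l]) for l in PAIN_LABELS]
        )
        baseline_n_eff[(key, row["hospital"])] = float(row["n_effective"])

    mort = _read_csv(path, "mortality.csv", ["age", "sex", "q"])
    age_min = int(mort["age"].min())
    mortality_q = {}
    for sex, grp in mort.groupby("sex"):
        grp = grp.sort_values("age")
        ages = grp["age"].to_numpy()
        if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
            raise BundleValidationError(f"mortality.csv: non-contiguous ages for {sex}")
        mortality_q[sex] = grp["q"].to_numpy(dtype=float)

    ex = _read_csv(path, "excess_mortality.csv", ["years_lo", "years_hi", "ratio"])
    excess = []
    for _, row in ex.iterrows():
        hi = None if pd.isna(row["years_hi"]) else int(row["years_hi"])
        excess.append((int(row["years_lo"]), hi, float(row["ratio"])))

    transitions, transition_n_eff = {}, {}
    for arm, fname in (("post_tkr", "transitions_tkr.csv"), ("exercise", "transitions_exercise.csv")):
        tr = _read_csv(
            path, fname, ["age_band", "sex", "from_state", "n_effective", *PAIN_LABELS]
        )
        for (band, sex), grp in tr.groupby(["age_band", "sex"]):
            P = np.zeros((3, 3))
            n_eff = np.zeros(3)
            for _, row in grp.iterrows():
                i = _state_index(row["from_state"], fname)
                P[i] = [float(row[l]) for l in PAIN_LABELS]
                n_eff[i] = float(row["n_effective"])
            transitions[(arm, (band, sex))] = P
            transition_n_eff[(arm, (band, sex))] = n_eff

    rev = _read_csv(path, "revision.csv", ["age_band", "sex", "year", "p_revision"])
    revision = {}
    for (band, sex), grp in rev.groupby(["age_band", "sex"]):
        grp = grp.sort_values("year")
        if list(grp["year"]) != list(range(1, K_MAX + 1)):
            raise BundleValidationError(
                f"revision.csv: stratum {(band, sex)} must cover years 1..{K_MAX}"
            )
        revision[(band, sex)] = grp["p_revision"].to_numpy(dtype=float)

    ut = _read_csv(path, "utilities.csv", ["age_band", "sex", "context", "state", "utility"])
    utilities = {}
    for _, row in ut.iterrows():
        key = ((row["age_band"], row["sex"]), row["context"])
        u = utilities.setdefault(key, np.zeros(3))
        u[_state_index(row["state"], "utilities.csv")] = float(row["utility"])

    inc = _read_csv(path, "incremental_utilities.csv", ["from_state", "to_state", "delta"])
    incremental = np.zeros((3, 3))
    for _, row in inc.iterrows():
        i = _state_index(row["from_state"], "incremental_utilities.csv")
        j = _state_index(row["to_state"], "incremental_utilities.csv")
        incremental[i, j] = float(row["delta"])

    inputs = ModelInputs(
        settings=settings,
        strata=strata,
        population=population,
        tkr_rate=tkr_rate,
        baseline_props=baseline_props,
        baseline_n_eff=baseline_n_eff,
        mortality_age_min=age_min,
        mortality_q=mortality_q,
        excess_intervals=excess,
        transitions=transitions,
        transition_n_eff=transition_n_eff,
        revision=revision,
        utilities=utilities,
        incremental_utility=incremental,
    )
    inputs.validate()
    return inputs


def write_bundle(inputs: ModelInputs, path: str | Path) -> Path:
    """Serialise a bundle back to the directory format (lossless round trip)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    keys = [s.key for s in inputs.strata]

    pd.DataFrame(
        [
            {
                "age_band": b,
                "sex": x,
                "population": inputs.population[(b, x)],
                "tkr_rate": inputs.tkr_rate[(b, x)],
            }
            for (b, x) in keys
        ]
    ).to_csv(path / "population.csv", index=False)

    rows = []
    for (key, h), p in sorted(inputs.baseline_props.items()):
        rows.append(
            {
                "age_band": key[0],
                "sex": key[1],
                "hospital": h,
                "n_effective": inputs.baseline_n_eff[(key, h)],
                **{l: p[i] for i, l in enumerate(PAIN_LABELS)},
            }
        )
    pd.DataFrame(rows).to_csv(path / "baseline_proportions.csv", index=False)

    rows = []
    for sex in sorted(inputs.mortality_q):
        for i, q in enumerate(inputs.mortality_q[sex]):
            rows.append({"age": inputs.mortality_age_min + i, "sex": sex, "q": q})
    pd.DataFrame(rows).to_csv(path / "mortality.csv", index=False)

    pd.DataFrame(
        [
            {"years_lo": lo, "years_hi": "" if hi is None else hi, "ratio": r}
            for lo, hi, r in inputs.excess_intervals
        ]
    ).to_csv(path / "excess_mortality.csv", index=False)

    for arm, fname in (("post_tkr", "transitions_tkr.csv"), ("exercise", "transitions_exercise.csv")):
        rows = []
        for key in keys:
            P = inputs.transitions[(arm, key)]
            n_eff = inputs.transition_n_eff[(arm, key)]
            for i, from_label in enumerate(PAIN_LABELS):
                rows.append(
                    {
                        "age_band": key[0],
                        "sex": key[1],
                        "from_state": from_label,
                        "n_effective": n_eff[i],
                        **{l: P[i, j] for j, l in enumerate(PAIN_LABELS)},
                    }
                )
        pd.DataFrame(rows).to_csv(path / fname, index=False)

    rows = []
    for key in keys:
        for year, p in enumerate(inputs.revision[key], start=1):
            rows.append(
                {"age_band": key[0], "sex": key[1], "year": year, "p_revision": p}
            )
    pd.DataFrame(rows).to_csv(path / "revision.csv", index=False)

    rows = []
    for key in keys:
        for ctx in CONTEXTS:
            for i, label in enumerate(PAIN_LABELS):
                rows.append(
                    {
                        "age_band": key[0],
                        "sex": key[1],
                        "context": ctx,
                        "state": label,
                        "utility": inputs.utilities[(key, ctx)][i],
                    }
                )
    pd.DataFrame(rows).to_csv(path / "utilities.csv", index=False)

    rows = []
    for i, fl in enumerate(PAIN_LABELS):
        for j, tl in enumerate(PAIN_LABELS):
            rows.append({"from_state": fl, "to_state": tl, "delta": inputs.incremental_utility[i, j]})
    pd.DataFrame(rows).to_csv(path / "incremental_utilities.csv", index=False)

    (path / "settings.json").write_text(
        json.dumps(inputs.settings.model_dump(), indent=1, sort_keys=True) + "\n"
    )
    return path
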