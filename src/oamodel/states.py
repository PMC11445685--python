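"""Health states, strata and the expanded (semi-Markov) state space.

The model tracks three alive pain states defined by the EQ-5D-5L pain
domain, plus an absorbing dead state.  Because revision risk and
post-surgical excess mortality depend on time since the primary knee
replacement, the cohort engine runs on an *expanded* state space with
yearly tunnel states:

* ``pre(origin, current)`` — not (yet) operated: enrolled in the
  education and exercise program.  The origin pain state is retained so
  that utilities can be computed as baseline utility of the origin plus
  the incremental utility of the origin -> current transition.
* ``post_primary[k](pain)`` — ``k`` whole years since the primary knee
  replacement, ``k = 1..K_MAX``; hazards are held at the ``K_MAX`` value
  beyond the last tunnel.
* ``post_revision[k](pain)`` — revised; ``k`` keeps counting years since
  the *primary* procedure so excess mortality stays keyed to it.
* ``dead`` — absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum


class HealthState(IntEnum):
    """Alive pain states (EQ-5D-5L pain domain) plus absorbing death."""

    NO_MILD = 0
    MODERATE = 1
    SEVERE_EXTREME = 2
    DEAD = 3


#: Alive pain states in canonical order.
PAIN_STATES = (HealthState.NO_MILD, HealthState.MODERATE, HealthState.SEVERE_EXTREME)
PAIN_LABELS = ("no_mild", "moderate", "severe_extreme")
N_PAIN = 3

AGE_BANDS = ("45-54", "55-64", "65-74", "75-84")
SEXES = ("female", "male")

#: Years of time-since-primary tunnel states; hazards are flat afterwards.
K_MAX = 20


@dataclass(frozen=True)
class Stratum:
    """An (age band, sex) population cell; the unit the engine iterates over."""

    age_band: str
    sex: str
    start_age: int

    def __post_init__(self) -> None:
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        lo, hi = (int(x) for x in self.age_band.split("-"))
        if not lo <= self.start_age <= hi:
            raise ValueError(
                f"start_age {self.start_age} outside band {self.age_band}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.age_band, self.sex)


def band_midpoint_age(age_band: str, offset: int = 5) -> int:
    """Default starting age for a band: lower bound plus ``offset`` (midpoint)."""
    lo = int(age_band.split("-")[0])
    return lo + offset


def default_strata(start_age_offset: int = 5) -> list[Stratum]:
    """The eight (age band x sex) strata covering the model population."""
    return [
        Stratum(band, sex, band_midpoint_age(band, start_age_offset))
        for band in AGE_BANDS
        for sex in SEXES
    ]


# ---------------------------------------------------------------------------
# Expanded state space layout (shared by every stratum)
# ---------------------------------------------------------------------------

PRE0 = 0                      # pre(origin, current): 9 states
PP0 = PRE0 + N_PAIN * N_PAIN  # post_primary[k](pain): K_MAX * 3 states
REV0 = PP0 + K_MAX * N_PAIN   # post_revision[k](pain): K_MAX * 3 states
DEAD = REV0 + K_MAX * N_PAIN  # absorbing
N_STATES = DEAD + 1


def idx_pre(origin: int, current: int) -> int:
    return PRE0 + N_PAIN * origin + current


def idx_pp(k: int, pain: int) -> int:
    """Post-primary tunnel index, ``k`` in 1..K_MAX."""
    return PP0 + N_PAIN * (k - 1) + pain


def idx_rev(k: int, pain: int) -> int:
    """Post-revision tunnel index, ``k`` = years since *primary*, 1..K_MAX."""
    return REV0 + N_PAIN * (k - 1) + pain
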