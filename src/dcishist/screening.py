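"""Mammography schedules and screen detection.

Two concerns live here: turning population dissemination patterns into
per-woman screen ages, and superimposing period-sensitive detection onto
an unscreened natural-history trajectory.  Detection is an absorbing
excision: the first positive screen replaces all later natural events.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InputError, InvalidParameterError
from .natural_history import Event, LifeHistory
from . import states as st

__all__ = [
    "SensitivitySchedule",
    "DisseminationSchedule",
    "default_sensitivity_schedule",
    "sensitivity_at",
    "generate_screen_schedule",
    "superimpose_screening",
    "PAPER_DCIS_SENSITIVITY",
    "SCREENING_START_YEAR",
]

SCREENING_START_YEAR = 1975

#: Period-specific mammography sensitivity for DCIS: half-open periods
#: [1975, 1985), [1985, 2000), [2000, 2010), [2010, inf).
PAPER_DCIS_SENSITIVITY = ((1975, 0.45), (1985, 0.55), (2000, 0.70), (2010, 0.85))


@dataclass(frozen=True)
class SensitivitySchedule:
    """Step function of per-screen sensitivity by calendar period.

    ``periods`` is an ordered tuple of (start_year, dcis_sensitivity,
    ibc_sensitivity); period ``i`` covers the half-open interval
    [start_i, start_{i+1}).
    """

    periods: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        starts = [p[0] for p in self.periods]
        if not starts:
            raise InvalidParameterError("sensitivity schedule needs at least one period")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise InvalidParameterError("period start years must be strictly increasing")
        for _, dcis, ibc in self.periods:
            if not (0 <= dcis <= 1 and 0 <= ibc <= 1):
                raise InvalidParameterError("sensitivities must lie in [0, 1]")

    def sensitivity_at(self, calendar_year: float, diagnosis: str) -> float:
        starts = [p[0] for p in self.periods]
        if calendar_year < starts[0]:
            raise InputError(
                f"calendar year {calendar_year} precedes first period ({starts[0]})"
            )
        i = bisect.bisect_right(starts, calendar_year) - 1
        if diagnosis == st.DIAG_DCIS:
            return self.periods[i][1]
        if diagnosis == st.DIAG_IBC:
            return self.periods[i][2]
        raise InputError(f"unknown diagnosis class {diagnosis!r}")

    def with_dcis_sensitivity(self, start_year: float, value: float) -> "SensitivitySchedule":
        """Copy with the DCIS sensitivity of one period replaced."""
        periods = tuple(
            (s, value if s == start_year else d, i) for s, d, i in self.periods
        )
        return replace(self, periods=periods)


def default_sensitivity_schedule(ibc_sensitivity: float = 0.85) -> SensitivitySchedule:
    """The four-period DCIS schedule with a flat IBC sensitivity."""
    return SensitivitySchedule(
        tuple((start, dcis, ibc_sensitivity) for start, dcis in PAPER_DCIS_SENSITIVITY)
    )


def sensitivity_at(schedule: SensitivitySchedule, calendar_year: float, diagnosis: str) -> float:
    """Sensitivity of the period containing ``calendar_year``."""
    return schedule.sensitivity_at(calendar_year, diagnosis)


class DisseminationSchedule:
    """Population screening uptake by birth cohort and calendar year.

    Backed by a long table with columns ``birth_year``, ``calendar_year``,
    ``start_probability`` (cumulative probability of having ever started
    screening by that year) and ``interval_years``.  Uptake must be
    non-decreasing through 2010 and constant afterwards.
    """

    def __init__(self, table: pd.DataFrame, first_screen_age: float = 40.0) -> None:
        required = {"birth_year", "calendar_year", "start_probability", "interval_years"}
        missing = required - set(table.columns)
        if missing:
            raise InputError(f"dissemination table missing columns {sorted(missing)}")
        if ((table["start_probability"] < 0) | (table["start_probability"] > 1)).any():
            raise InputError("start probabilities must lie in [0, 1]")
        if (table["interval_years"] <= 0).any():
            raise InputError("screening intervals must be positive")
        self.first_screen_age = float(first_screen_age)
        self._cohorts: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for by, grp in table.groupby("birth_year"):
            grp = grp.sort_values("calendar_year")
            years = grp["calendar_year"].to_numpy(dtype=float)
            probs = grp["start_probability"].to_numpy(dtype=float)
            until_2010 = probs[years <= 2010]
            if np.any(np.diff(until_2010) < -1e-12):
                raise InputError(f"uptake decreases before 2010 for cohort {by}")
            after = probs[years >= 2010]
            if after.size and np.ptp(after) > 1e-9:
                raise InputError(f"uptake not constant after 2010 for cohort {by}")
            self._cohorts[int(by)] = (
                years,
                probs,
                grp["interval_years"].to_numpy(dtype=float),
            )
        if not self._cohorts:
            raise InputError("dissemination table is empty")
        self._cohort_keys = np.array(sorted(self._cohorts), dtype=float)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DisseminationSchedule":
        return cls(pd.read_csv(path), **kwargs)

    def _rows(self, birth_year: float):
        idx = int(np.argmin(np.abs(self._cohort_keys - birth_year)))
        return self._cohorts[int(self._cohort_keys[idx])]

    def start_prob(self, birth_year: float, calendar_year: float) -> float:
        years, probs, _ = self._rows(birth_year)
        if calendar_year < years[0]:
            return 0.0
        i = int(np.searchsorted(years, calendar_year, side="right")) - 1
        return float(probs[i])

    def interval_years(self, birth_year: float, calendar_year: float) -> float:
        years, _, intervals = self._rows(birth_year)
        i = int(np.clip(np.searchsorted(years, calendar_year, side="right") - 1, 0, len(years) - 1))
        return float(intervals[i])


def generate_screen_schedule(
    dissem: DisseminationSchedule,
    birth_year: float,
    death_age: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Realize one woman's screen ages from the dissemination pattern.

    A single uniform draw decides when (if ever) the woman starts
    screening: she starts in the first eligible calendar year whose
    cumulative start probability reaches the draw, then screens at the
    cohort's inter-screen interval until death.  All screens satisfy
    ``age < death_age`` and calendar time >= 1975.
    """
    u = rng.random()
    first_year = int(math.ceil(max(SCREENING_START_YEAR, birth_year + dissem.first_screen_age)))
    last_year = int(math.floor(birth_year + death_age))
    start_year = None
    for year in range(first_year, last_year + 1):
        if dissem.start_prob(birth_year, year) >= u and u > 0:
            start_year = year
            break
    if start_year is None:
        return np.empty(0)
    start_age = start_year - birth_year + rng.random()
    if start_age >= death_age:
        return np.empty(0)
    interval = dissem.interval_years(birth_year, start_year)
    n = int(math.floor((death_age - start_age) / interval)) + 1
    ages = start_age + interval * np.arange(n)
    return ages[ages < death_age]


def superimpose_screening(
    history: LifeHistory,
    screens,
    sens: SensitivitySchedule,
    rng: np.random.Generator,
) -> LifeHistory:
    """Overlay screen detection on an unscreened trajectory.

    Walks the screens in order.  At a screen falling inside the lesion's
    screen-detectable DCIS window, detection occurs with the DCIS
    sensitivity of that calendar period; inside the preclinical-IBC
    window, with the IBC sensitivity.  The first detection appends an
    absorbing ``screen_detected_*`` event and removes all later natural
    events (the lesion is excised); other-cause death is retained.
    Undetected screens leave the trajectory unchanged.
    """
    screens = np.asarray(screens, dtype=float)
    if screens.size and np.any(np.diff(screens) <= 0):
        raise InputError("screen ages must be strictly increasing")
    if screens.size == 0:
        return history

    sd_window = history.interval_of(st.DCIS_SCREEN_DETECTABLE)
    ibc_window = history.interval_of(st.IBC_PRECLINICAL)
    death_age = history.other_cause_death_age

    for age in screens:
        if age >= death_age:
            break
        year = history.birth_year + age
        if sd_window and sd_window[0] <= age < sd_window[1]:
            prob = sens.sensitivity_at(year, st.DIAG_DCIS)
            detected_state = st.SCREEN_DETECTED_DCIS
        elif ibc_window and ibc_window[0] <= age < ibc_window[1]:
            prob = sens.sensitivity_at(year, st.DIAG_IBC)
            detected_state = st.SCREEN_DETECTED_IBC
        else:
            continue
        if rng.random() < prob:
            kept = [ev for ev in history.events if ev.age < age and ev.state != st.DEATH_OTHER]
            kept.append(Event(detected_state, age))
            kept.append(Event(st.DEATH_OTHER, death_age))
            return LifeHistory(history.woman_id, history.birth_year, death_age, kept)
    return history
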