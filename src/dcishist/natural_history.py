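"""Multi-state natural history of preclinical DCIS.

The model tracks a single lesion per woman through an undetectable
preclinical state, an optional screen-detectable state, and exits toward
preclinical/clinical invasive breast cancer (IBC), clinical DCIS, or
regression.  Six canonical submodels cross three undetectable-to-
screen-detectable progression fractions (30/50/80%) with regression
allowed or prohibited.

Dwell times are path-conditional exponentials: the exit path is drawn
first, then the dwell time from an exponential with the path-specific
mean sojourn time.  This reproduces distinct per-path mean sojourn times
within one submodel, which independent competing exponential clocks
cannot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ConfigConflictError, InvalidParameterError
from . import states as st

__all__ = [
    "SubmodelConfig",
    "NaturalHistoryParams",
    "PiecewiseConstantHazard",
    "Event",
    "LifeHistory",
    "sample_onset_age",
    "sample_undetectable_fate",
    "sample_screen_detectable_fate",
    "simulate_lesion",
    "SUBMODEL_FRACTIONS",
]

#: Canonical progression fractions by submodel family.
SUBMODEL_FRACTIONS = {"1": 0.30, "2": 0.50, "3": 0.80}

#: Destinations out of the undetectable state.
DEST_SCREEN_DETECTABLE = "screen_detectable"
DEST_IBC_DIRECT = "ibc_direct"
DEST_INDOLENT = "indolent"
DEST_REGRESSION = "regression"  # only with the optional undetectable-regression switch


@dataclass(frozen=True)
class SubmodelConfig:
    """One of the six natural-history submodels (or an arbitrary variant).

    Parameters
    ----------
    submodel_id : str
        Label such as ``"2a"``.  The digit selects the progression
        fraction (1->30%, 2->50%, 3->80%); the letter selects regression
        (``a`` prohibited, ``b`` allowed).
    frac_to_screen_detectable : float
        Proportion of undetectable lesions that become screen-detectable.
    regression_allowed : bool
        Whether the screen-detectable state may exit to regression.
    """

    submodel_id: str
    frac_to_screen_detectable: float
    regression_allowed: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_to_screen_detectable <= 1.0:
            raise InvalidParameterError(
                f"frac_to_screen_detectable must be in [0, 1], "
                f"got {self.frac_to_screen_detectable}"
            )

    @classmethod
    def from_id(cls, submodel_id: str) -> "SubmodelConfig":
        """Build one of the six canonical submodels from its label."""
        sid = submodel_id.strip().lower()
        if len(sid) != 2 or sid[0] not in SUBMODEL_FRACTIONS or sid[1] not in "ab":
            raise InvalidParameterError(f"unknown submodel id {submodel_id!r}")
        return cls(
            submodel_id=sid,
            frac_to_screen_detectable=SUBMODEL_FRACTIONS[sid[0]],
            regression_allowed=sid[1] == "b",
        )


class PiecewiseConstantHazard:
    """Piecewise-constant age hazard with a log-linear birth-cohort trend.

    The hazard at age ``a`` for birth year ``b`` is
    ``values[band(a)] * exp(cohort_log_slope * (b - cohort_ref_year))``.
    The last band extends to infinity.
    """

    def __init__(
        self,
        breaks: Sequence[float],
        values: Sequence[float],
        cohort_log_slope: float = 0.0,
        cohort_ref_year: float = 1950.0,
    ) -> None:
        breaks = [float(x) for x in breaks]
        values = [float(v) for v in values]
        if len(breaks) != len(values) or not breaks:
            raise InvalidParameterError("breaks and values must have equal nonzero length")
        if breaks[0] != 0.0:
            raise InvalidParameterError("first break must be age 0")
        if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
            raise InvalidParameterError("breaks must be strictly increasing")
        if any(v < 0 for v in values):
            raise InvalidParameterError("hazard values must be nonnegative")
        self.breaks = breaks
        self.values = values
        self.cohort_log_slope = float(cohort_log_slope)
        self.cohort_ref_year = float(cohort_ref_year)

    @classmethod
    def constant(cls, hazard: float) -> "PiecewiseConstantHazard":
        return cls([0.0], [hazard])

    def _cohort_scale(self, birth_year: float) -> float:
        return math.exp(self.cohort_log_slope * (birth_year - self.cohort_ref_year))

    def rate(self, age: float, birth_year: float) -> float:
        """Hazard per woman-year at a given age and birth year."""
        if age < 0:
            return 0.0
        i = np.searchsorted(self.breaks, age, side="right") - 1
        return self.values[i] * self._cohort_scale(birth_year)

    def cumulative(self, age: float, birth_year: float) -> float:
        """Integrated hazard over [0, age]."""
        scale = self._cohort_scale(birth_year)
        total = 0.0
        for i, lo in enumerate(self.breaks):
            hi = self.breaks[i + 1] if i + 1 < len(self.breaks) else math.inf
            hi = min(hi, age)
            if hi <= lo:
                break
            total += self.values[i] * (hi - lo)
        return total * scale

    def sample(self, birth_year: float, death_age: float, rng: np.random.Generator):
        """Draw an event age from the hazard, truncated by ``death_age``.

        Returns None when no event occurs before death.
        """
        target = rng.exponential(1.0)
        scale = self._cohort_scale(birth_year)
        acc = 0.0
        for i, lo in enumerate(self.breaks):
            hi = self.breaks[i + 1] if i + 1 < len(self.breaks) else math.inf
            hi = min(hi, death_age)
            if hi <= lo:
                break
            rate = self.values[i] * scale
            seg = rate * (hi - lo)
            if rate > 0 and acc + seg >= target:
                age = lo + (target - acc) / rate
                return age if age < death_age else None
            acc += seg
            if hi >= death_age:
                break
        return None

    def scaled(self, factor: float) -> "PiecewiseConstantHazard":
        """Return a copy with all band values multiplied by ``factor``."""
        if factor < 0:
            raise InvalidParameterError("hazard scale factor must be nonnegative")
        return PiecewiseConstantHazard(
            self.breaks,
            [v * factor for v in self.values],
            self.cohort_log_slope,
            self.cohort_ref_year,
        )


@dataclass(frozen=True)
class NaturalHistoryParams:
    """All rates, probabilities, and mean sojourn times of the state graph.

    ``p1``, ``p2``, ``p3`` are the exit-path probabilities from the
    screen-detectable state (to preclinical IBC, clinical DCIS, and
    regression respectively); ``mst1``/``mst2``/``mst3`` are the matching
    path-conditional mean sojourn times in years.  ``mst3`` may be None
    when ``p3 == 0``.
    """

    onset_hazard: PiecewiseConstantHazard
    undetectable_mean_dwell: float
    undetectable_direct_to_ibc_frac: float
    p1: float
    p2: float
    p3: float
    mst1: float
    mst2: float
    mst3: float | None
    ibc_preclinical_mean_dwell: float
    #: Optional switch: fraction of the indolent remainder of the
    #: undetectable state that regresses instead (off by default).
    undetectable_regression_frac: float = 0.0

    def __post_init__(self) -> None:
        probs = (self.p1, self.p2, self.p3)
        if any(p < 0 or p > 1 for p in probs):
            raise InvalidParameterError("path probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise InvalidParameterError(
                f"p1 + p2 + p3 must equal 1, got {sum(probs)!r}"
            )
        if self.undetectable_mean_dwell <= 0:
            raise InvalidParameterError("undetectable_mean_dwell must be > 0")
        if self.ibc_preclinical_mean_dwell <= 0:
            raise InvalidParameterError("ibc_preclinical_mean_dwell must be > 0")
        if not 0 <= self.undetectable_direct_to_ibc_frac <= 1:
            raise InvalidParameterError("undetectable_direct_to_ibc_frac must be in [0, 1]")
        if not 0 <= self.undetectable_regression_frac <= 1:
            raise InvalidParameterError("undetectable_regression_frac must be in [0, 1]")
        for name, mst, p in (("mst1", self.mst1, self.p1), ("mst2", self.mst2, self.p2)):
            if p > 0 and (mst is None or mst <= 0):
                raise InvalidParameterError(f"{name} must be > 0 when its path is reachable")
        if self.p3 > 0 and (self.mst3 is None or self.mst3 <= 0):
            raise InvalidParameterError("mst3 must be > 0 when p3 > 0")

    def check_config(self, config: SubmodelConfig) -> None:
        """Raise when the parameter vector contradicts the submodel."""
        if self.p3 > 0 and not config.regression_allowed:
            raise ConfigConflictError(
                f"p3={self.p3} > 0 but submodel {config.submodel_id!r} prohibits regression"
            )

    def with_paths(self, p1: float, p2: float, p3: float) -> "NaturalHistoryParams":
        return replace(self, p1=p1, p2=p2, p3=p3)


class Event(NamedTuple):
    state: str
    age: float


@dataclass
class LifeHistory:
    """Ordered state-transition events of one woman in one universe."""

    woman_id: int
    birth_year: float
    other_cause_death_age: float
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = [Event(*e) for e in self.events]
        ages = [e.age for e in self.events]
        if any(a2 <= a1 for a1, a2 in zip(ages, ages[1:])):
            raise InvalidParameterError("event ages must be strictly increasing")
        if any(a > self.other_cause_death_age for a in ages):
            raise InvalidParameterError("no event may follow other-cause death")

    # -- queries -----------------------------------------------------------

    def state_at(self, age: float) -> str:
        """State occupied at ``age`` (half-open [event, next-event) windows)."""
        state = st.NO_BC
        for ev in self.events:
            if ev.age <= age:
                state = ev.state
            else:
                break
        return state

    def first_event(self, state: str) -> Event | None:
        for ev in self.events:
            if ev.state == state:
                return ev
        return None

    def has_state(self, state: str) -> bool:
        return any(ev.state == state for ev in self.events)

    def interval_of(self, state: str) -> tuple[float, float] | None:
        """[entry, exit) ages of the first occupancy of ``state``, or None."""
        for i, ev in enumerate(self.events):
            if ev.state == state:
                exit_age = (
                    self.events[i + 1].age
                    if i + 1 < len(self.events)
                    else self.other_cause_death_age
                )
                return (ev.age, exit_age)
        return None

    def check_edges(self) -> None:
        """Assert every consecutive event pair is an allowed transition."""
        prev = st.NO_BC
        for ev in self.events:
            if (prev, ev.state) not in st.ALLOWED_EDGES and ev.state != st.DEATH_OTHER:
                raise InvalidParameterError(f"illegal transition {prev} -> {ev.state}")
            prev = ev.state


# ---------------------------------------------------------------------------
# Sampling operations
# ---------------------------------------------------------------------------


def sample_onset_age(
    params: NaturalHistoryParams,
    birth_year: float,
    death_age: float,
    rng: np.random.Generator,
):
    """Draw the age of entry into the undetectable preclinical state.

    Returns None when no onset occurs before other-cause death.
    """
    return params.onset_hazard.sample(birth_year, death_age, rng)


def sample_undetectable_fate(
    config: SubmodelConfig,
    params: NaturalHistoryParams,
    rng: np.random.Generator,
) -> tuple[str, float]:
    """Draw the destination and dwell time out of the undetectable state.

    Destination is screen-detectable with probability
    ``frac_to_screen_detectable``; the remainder splits between direct
    progression to preclinical IBC and indolence (never leaving the
    state, dwell = inf).  Dwell times are exponential with mean
    ``undetectable_mean_dwell``.
    """
    u = rng.random()
    dwell = rng.exponential(params.undetectable_mean_dwell)
    if u < config.frac_to_screen_detectable:
        return DEST_SCREEN_DETECTABLE, dwell
    v = rng.random()
    if v < params.undetectable_direct_to_ibc_frac:
        return DEST_IBC_DIRECT, dwell
    if params.undetectable_regression_frac > 0:
        w = rng.random()
        if w < params.undetectable_regression_frac:
            return DEST_REGRESSION, dwell
    return DEST_INDOLENT, math.inf


def sample_screen_detectable_fate(
    config: SubmodelConfig,
    params: NaturalHistoryParams,
    rng: np.random.Generator,
) -> tuple[str, float]:
    """Draw the exit path (P1/P2/P3) and the path-conditional dwell time."""
    params.check_config(config)
    u = rng.random()
    if u < params.p1:
        path, mst = st.PATH_P1, params.mst1
    elif u < params.p1 + params.p2:
        path, mst = st.PATH_P2, params.mst2
    else:
        path, mst = st.PATH_P3, params.mst3
    dwell = rng.exponential(mst)
    return path, dwell


def simulate_lesion(
    config: SubmodelConfig,
    params: NaturalHistoryParams,
    birth_year: float,
    death_age: float,
    rng: np.random.Generator,
    woman_id: int = 0,
) -> LifeHistory:
    """Sample one complete unscreened trajectory truncated at death.

    Chains onset -> undetectable fate -> (optionally) screen-detectable
    fate -> (on the invasive paths) preclinical-IBC dwell -> clinical
    IBC.  Every event at or after the other-cause death age is dropped
    and the trajectory ends with a ``death_other`` event.
    """
    events: list[Event] = []
    onset = sample_onset_age(params, birth_year, death_age, rng)
    if onset is not None and onset < death_age:
        events.append(Event(st.DCIS_UNDETECTABLE, onset))
        dest, dwell = sample_undetectable_fate(config, params, rng)
        t = onset + dwell
        if dest == DEST_SCREEN_DETECTABLE and t < death_age:
            events.append(Event(st.DCIS_SCREEN_DETECTABLE, t))
            path, sd_dwell = sample_screen_detectable_fate(config, params, rng)
            t2 = t + sd_dwell
            if t2 < death_age:
                events.append(Event(st.PATH_EXIT_STATE[path], t2))
                if path == st.PATH_P1:
                    t3 = t2 + rng.exponential(params.ibc_preclinical_mean_dwell)
                    if t3 < death_age:
                        events.append(Event(st.IBC_CLINICAL, t3))
        elif dest == DEST_IBC_DIRECT and t < death_age:
            events.append(Event(st.IBC_PRECLINICAL, t))
            t3 = t + rng.exponential(params.ibc_preclinical_mean_dwell)
            if t3 < death_age:
                events.append(Event(st.IBC_CLINICAL, t3))
        elif dest == DEST_REGRESSION and t < death_age:
            events.append(Event(st.REGRESSED, t))
        # indolent: lesion stays in the undetectable state until death
    events.append(Event(st.DEATH_OTHER, death_age))
    return LifeHistory(woman_id, birth_year, death_age, events)
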