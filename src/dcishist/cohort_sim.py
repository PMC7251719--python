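"""Parallel-universe population engine.

Every woman is simulated twice — once without screening and once with —
sharing all natural-history randomness.  Common random numbers are
implemented as per-woman substreams keyed by (master seed, woman_id),
with separate substreams for natural history and for screening
attendance/detection, so changing the screening arm never perturbs the
natural history and per-woman results are independent of simulation
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .natural_history import LifeHistory, NaturalHistoryParams, SubmodelConfig, simulate_lesion
from .screening import (
    DisseminationSchedule,
    SensitivitySchedule,
    generate_screen_schedule,
    superimpose_screening,
)

__all__ = [
    "LifeTable",
    "PopulationSpec",
    "WomanPair",
    "PairedEventLog",
    "simulate_population",
    "iter_population",
]

UNIVERSES = ("unscreened", "screened")

# substream indices under the (seed, woman_id) key
_STREAM_NATURAL = 0
_STREAM_SCREENING = 1


class LifeTable:
    """Annual other-cause death probabilities by birth cohort and age.

    Sampling uses inverse-CDF on the annual probabilities with uniform
    interpolation within the year of death.  Women surviving the whole
    table die at its final age (tables should end with probability 1).
    """

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"birth_year", "age", "annual_other_cause_death_prob"}
        missing = required - set(table.columns)
        if missing:
            raise InputError(f"life table missing columns {sorted(missing)}")
        q = table["annual_other_cause_death_prob"]
        if ((q < 0) | (q > 1)).any() or q.isna().any():
            raise InputError("death probabilities must lie in [0, 1]")
        self._cohorts: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for by, grp in table.groupby("birth_year"):
            grp = grp.sort_values("age")
            ages = grp["age"].to_numpy(dtype=float)
            if not np.array_equal(ages, np.arange(len(ages))):
                raise InputError(f"cohort {by}: ages must be 0..A-1 with no gaps")
            qv = grp["annual_other_cause_death_prob"].to_numpy(dtype=float)
            surv = np.concatenate([[1.0], np.cumprod(1.0 - qv)])  # S[a], len A+1
            death_cdf = 1.0 - surv[1:]  # P(die before age a+1)
            self._cohorts[int(by)] = (qv, surv, death_cdf)
        if not self._cohorts:
            raise InputError("life table is empty")
        self._cohort_keys = np.array(sorted(self._cohorts), dtype=float)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def _rows(self, birth_year: float):
        idx = int(np.argmin(np.abs(self._cohort_keys - birth_year)))
        return self._cohorts[int(self._cohort_keys[idx])]

    def max_age(self, birth_year: float) -> float:
        q, _, _ = self._rows(birth_year)
        return float(len(q))

    def cdf(self, birth_year: float, age: float) -> float:
        """Continuous death-age CDF implied by the sampling scheme."""
        q, surv, _ = self._rows(birth_year)
        if age <= 0:
            return 0.0
        if age >= len(q):
            return 1.0
        a = int(age)
        frac = age - a
        return float(1.0 - surv[a] + surv[a] * q[a] * frac)

    def sample_death_age(self, birth_year: float, rng: np.random.Generator) -> float:
        q, surv, death_cdf = self._rows(birth_year)
        u = rng.random()
        a = int(np.searchsorted(death_cdf, u, side="left"))
        if a >= len(q):  # survived the whole table
            return float(len(q))
        mass = surv[a] * q[a]
        frac = (u - (1.0 - surv[a])) / mass if mass > 0 else 0.0
        return float(a + min(max(frac, 0.0), 1.0 - 1e-12))


@dataclass(frozen=True)
class PopulationSpec:
    """Everything needed to simulate one paired population."""

    config: SubmodelConfig
    params: NaturalHistoryParams
    life_table: LifeTable
    sensitivity: SensitivitySchedule
    dissemination: DisseminationSchedule
    cohorts: Sequence[int] = tuple(range(1890, 1997))
    cohort_weights: Sequence[float] | None = None
    n_women: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_women < 1:
            raise InputError("n_women must be >= 1")
        if not self.cohorts:
            raise InputError("at least one birth cohort is required")
        if self.cohort_weights is not None and len(self.cohort_weights) != len(self.cohorts):
            raise InputError("cohort_weights must match cohorts in length")

    def with_(self, **kwargs) -> "PopulationSpec":
        return replace(self, **kwargs)


@dataclass
class WomanPair:
    """One woman's two universes, linked by woman_id."""

    woman_id: int
    birth_year: int
    other_cause_death_age: float
    unscreened: LifeHistory
    screened: LifeHistory


@dataclass
class PairedEventLog:
    pairs: list[WomanPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def histories(self, universe: str) -> Iterator[LifeHistory]:
        if universe not in UNIVERSES:
            raise InputError(f"unknown universe {universe!r}")
        for p in self.pairs:
            yield p.unscreened if universe == "unscreened" else p.screened

    def to_events(self) -> pd.DataFrame:
        """Long-format event table (one row per event per universe)."""
        rows = []
        for p in self.pairs:
            for universe in UNIVERSES:
                hist = p.unscreened if universe == "unscreened" else p.screened
                for ev in hist.events:
                    rows.append(
                        (
                            p.woman_id,
                            universe,
                            p.birth_year,
                            ev.state,
                            ev.age,
                            p.birth_year + ev.age,
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=["woman_id", "universe", "birth_year", "state", "age", "calendar_year"],
        )


def assign_cohorts(
    cohorts: Sequence[int], weights: Sequence[float] | None, n_women: int
) -> np.ndarray:
    """Deterministic largest-remainder apportionment of women to cohorts."""
    cohorts = np.asarray(cohorts, dtype=int)
    if weights is None:
        w = np.full(len(cohorts), 1.0 / len(cohorts))
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise InputError("cohort weights must be nonnegative with positive sum")
        w = w / w.sum()
    ideal = w * n_women
    counts = np.floor(ideal).astype(int)
    remainder = n_women - counts.sum()
    if remainder > 0:
        order = np.argsort(-(ideal - counts), kind="stable")
        counts[order[:remainder]] += 1
    return np.repeat(cohorts, counts)


def _rng_for(seed: int, woman_id: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, woman_id, stream])


def iter_population(spec: PopulationSpec) -> Iterator[WomanPair]:
    """Stream woman pairs one at a time (memory-light for large n)."""
    birth_years = assign_cohorts(spec.cohorts, spec.cohort_weights, spec.n_women)
    spec.params.check_config(spec.config)
    for woman_id, birth_year in enumerate(birth_years):
        yield simulate_woman(spec, woman_id, int(birth_year))


def simulate_woman(spec: PopulationSpec, woman_id: int, birth_year: int) -> WomanPair:
    rng_nat = _rng_for(spec.seed, woman_id, _STREAM_NATURAL)
    rng_scr = _rng_for(spec.seed, woman_id, _STREAM_SCREENING)
    death_age = spec.life_table.sample_death_age(birth_year, rng_nat)
    unscreened = simulate_lesion(
        spec.config, spec.params, birth_year, death_age, rng_nat, woman_id=woman_id
    )
    screens = generate_screen_schedule(spec.dissemination, birth_year, death_age, rng_scr)
    screened = superimpose_screening(unscreened, screens, spec.sensitivity, rng_scr)
    return WomanPair(woman_id, birth_year, death_age, unscreened, screened)


def simulate_population(spec: PopulationSpec) -> PairedEventLog:
    """Simulate the full paired population described by ``spec``."""
    return PairedEventLog(list(iter_population(spec)))
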