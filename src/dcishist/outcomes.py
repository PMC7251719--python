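"""Outcome measures computed from paired event logs.

Incidence tables (age-specific and directly age-standardized over the
5-year groups 30-79), empirical mean sojourn times per exit path,
progression proportions by age at entry, and counterfactual
overdiagnosis from the paired universes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_sim import PairedEventLog
from .errors import ConsistencyError, InputError
from .natural_history import LifeHistory
from . import states as st

__all__ = [
    "IncidenceTable",
    "MstEstimate",
    "PathStat",
    "OverdiagnosisReport",
    "equal_standard_weights",
    "compute_incidence",
    "estimate_mst",
    "progression_proportions",
    "compute_overdiagnosis",
]


def equal_standard_weights() -> dict[str, float]:
    """Equal weights over the ten 5-year groups 30-79."""
    return {g: 1.0 / len(st.AGE_GROUPS) for g in st.AGE_GROUPS}


def _validate_weights(weights: dict[str, float]) -> dict[str, float]:
    if set(weights) != set(st.AGE_GROUPS):
        raise InputError(f"weights must cover exactly the groups {list(st.AGE_GROUPS)}")
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise InputError(f"standard-population weights must sum to 1, got {total}")
    return weights


def first_diagnosis(history: LifeHistory):
    """First diagnosis event of a trajectory, or None.

    Diagnosis events are clinical DCIS, clinical IBC, and the two
    screen-detected absorbing states.
    """
    for ev in history.events:
        if ev.state in st.DIAGNOSIS_EVENTS:
            return ev
    return None


@dataclass
class IncidenceTable:
    """Counts, women-years and rates by year x age group x diagnosis x mode.

    ``age_adjusted`` holds one row per (year, diagnosis) with the
    directly standardized rate per 100,000 (modes pooled).
    """

    cells: pd.DataFrame
    age_adjusted: pd.DataFrame
    weights: dict[str, float]

    def age_adjusted_rate(self, diagnosis: str) -> pd.Series:
        sub = self.age_adjusted[self.age_adjusted["diagnosis"] == diagnosis]
        return sub.set_index("year")["rate_per_100k"].sort_index()

    def total_count(self, diagnosis: str | None = None, mode: str | None = None) -> float:
        sub = self.cells
        if diagnosis is not None:
            sub = sub[sub["diagnosis"] == diagnosis]
        if mode is not None:
            sub = sub[sub["mode"] == mode]
        return float(sub["count"].sum())

    @classmethod
    def from_observed_csv(cls, path, weights: dict[str, float] | None = None) -> "IncidenceTable":
        """Read an observed-incidence CSV (year, age_group, diagnosis, rate_per_100k)."""
        df = pd.read_csv(path)
        return cls.from_observed_frame(df, weights)

    @classmethod
    def from_observed_frame(
        cls, df: pd.DataFrame, weights: dict[str, float] | None = None
    ) -> "IncidenceTable":
        required = {"year", "age_group", "diagnosis", "rate_per_100k"}
        missing = required - set(df.columns)
        if missing:
            raise InputError(f"observed incidence missing columns {sorted(missing)}")
        weights = _validate_weights(weights or equal_standard_weights())
        df = df.copy()
        df["weight"] = df["age_group"].map(weights)
        if df["weight"].isna().any():
            bad = df.loc[df["weight"].isna(), "age_group"].unique()
            raise InputError(f"unknown age groups in observed incidence: {bad}")
        adj = (
            df.assign(w_rate=df["rate_per_100k"] * df["weight"])
            .groupby(["year", "diagnosis"], as_index=False)["w_rate"]
            .sum()
            .rename(columns={"w_rate": "rate_per_100k"})
        )
        cells = df.drop(columns=["weight"])
        cells["count"] = np.nan
        cells["women_years"] = np.nan
        cells["mode"] = "all"
        return cls(cells=cells, age_adjusted=adj, weights=weights)


def compute_incidence(
    log: PairedEventLog,
    universe: str,
    weights: dict[str, float] | None = None,
) -> IncidenceTable:
    """Tabulate incidence in one universe of a paired event log.

    Women-years accumulate from age 30 until the earliest of first
    diagnosis, other-cause death, and age 80; diagnosis events outside
    ages 30-79 are excluded (they fall outside the adjustment range).
    """
    weights = _validate_weights(weights or equal_standard_weights())
    histories = list(log.histories(universe))
    n = len(histories)
    if n == 0:
        empty = pd.DataFrame(
            columns=["year", "age_group", "diagnosis", "mode", "count", "women_years", "rate_per_100k"]
        )
        adj = pd.DataFrame(columns=["year", "diagnosis", "rate_per_100k"])
        return IncidenceTable(empty, adj, weights)

    birth = np.array([h.birth_year for h in histories], dtype=int)
    end_age = np.empty(n)
    diag_rows = []  # (year, group_idx, diag_idx, mode_idx)
    for i, h in enumerate(histories):
        ev = first_diagnosis(h)
        end_age[i] = min(h.other_cause_death_age, ev.age if ev else math.inf)
        if ev is not None and st.ADJUSTMENT_AGE_MIN <= ev.age < st.ADJUSTMENT_AGE_MAX:
            diag, mode = st.DIAGNOSIS_EVENTS[ev.state]
            year = int(birth[i] + ev.age)
            group = (int(ev.age) - st.ADJUSTMENT_AGE_MIN) // st.AGE_GROUP_WIDTH
            diag_rows.append((year, group, diag, mode))

    y0 = int(birth.min() + st.ADJUSTMENT_AGE_MIN)
    y1 = int(birth.max() + st.ADJUSTMENT_AGE_MAX)
    n_years = y1 - y0 + 1
    n_groups = len(st.AGE_GROUPS)

    wy = np.zeros((n_years, n_groups))
    for age in range(st.ADJUSTMENT_AGE_MIN, st.ADJUSTMENT_AGE_MAX):
        exposure = np.clip(end_age - age, 0.0, 1.0)
        years_idx = birth + age - y0
        np.add.at(wy[:, (age - st.ADJUSTMENT_AGE_MIN) // st.AGE_GROUP_WIDTH], years_idx, exposure)

    diagnoses = (st.DIAG_DCIS, st.DIAG_IBC)
    modes = ("clinical", "screen")
    counts = {(d, m): np.zeros((n_years, n_groups)) for d in diagnoses for m in modes}
    for year, group, diag, mode in diag_rows:
        counts[(diag, mode)][year - y0, group] += 1

    rows = []
    group_labels = st.AGE_GROUPS
    for yi in range(n_years):
        for gi in range(n_groups):
            denom = wy[yi, gi]
            if denom <= 0:
                continue
            for d in diagnoses:
                for m in modes:
                    c = counts[(d, m)][yi, gi]
                    rows.append(
                        (y0 + yi, group_labels[gi], d, m, c, denom, 1e5 * c / denom)
                    )
    cells = pd.DataFrame(
        rows,
        columns=["year", "age_group", "diagnosis", "mode", "count", "women_years", "rate_per_100k"],
    )

    w_vec = np.array([weights[g] for g in group_labels])
    adj_rows = []
    for d in diagnoses:
        pooled = counts[(d, "clinical")] + counts[(d, "screen")]
        with np.errstate(invalid="ignore", divide="ignore"):
            group_rates = np.where(wy > 0, 1e5 * pooled / np.where(wy > 0, wy, 1.0), 0.0)
        adj = group_rates @ w_vec
        has_exposure = wy.sum(axis=1) > 0
        for yi in np.nonzero(has_exposure)[0]:
            adj_rows.append((y0 + int(yi), d, float(adj[yi])))
    age_adjusted = pd.DataFrame(adj_rows, columns=["year", "diagnosis", "rate_per_100k"])
    return IncidenceTable(cells=cells, age_adjusted=age_adjusted, weights=weights)


@dataclass(frozen=True)
class PathStat:
    mean: float
    se: float
    n: int


@dataclass
class MstEstimate:
    """Per-exit-path empirical mean sojourn time in the screen-detectable state.

    Paths with zero completed episodes carry None (absent, not zero).
    Episodes censored by other-cause death while still in the state are
    counted in ``n_censored`` and excluded from the means.
    """

    paths: dict[str, PathStat | None]
    n_censored: int

    def pooled_mean(self) -> float | None:
        dwells_n = [(p.mean * p.n, p.n) for p in self.paths.values() if p is not None]
        total_n = sum(n for _, n in dwells_n)
        if total_n == 0:
            return None
        return sum(s for s, _ in dwells_n) / total_n


_EXIT_TO_PATH = {
    st.IBC_PRECLINICAL: st.PATH_P1,
    st.CLINICAL_DCIS: st.PATH_P2,
    st.REGRESSED: st.PATH_P3,
}


def _screen_detectable_episodes(histories) -> tuple[dict[str, list[tuple[float, float]]], int]:
    """Collect (entry age, dwell) per exit path; count death-censored episodes."""
    by_path: dict[str, list[tuple[float, float]]] = {p: [] for p in st.PATHS}
    censored = 0
    for h in histories:
        for i, ev in enumerate(h.events):
            if ev.state != st.DCIS_SCREEN_DETECTABLE:
                continue
            nxt = h.events[i + 1] if i + 1 < len(h.events) else None
            if nxt is None or nxt.state == st.DEATH_OTHER:
                censored += 1
            elif nxt.state in _EXIT_TO_PATH:
                by_path[_EXIT_TO_PATH[nxt.state]].append((ev.age, nxt.age - ev.age))
            else:  # screen-detected: excised, dwell interrupted
                censored += 1
            break
    return by_path, censored


def estimate_mst(log: PairedEventLog, universe: str = "unscreened") -> MstEstimate:
    """Empirical mean sojourn time per exit path (unscreened by default)."""
    by_path, censored = _screen_detectable_episodes(log.histories(universe))
    paths: dict[str, PathStat | None] = {}
    for p in st.PATHS:
        dwells = np.array([d for _, d in by_path[p]])
        if dwells.size == 0:
            paths[p] = None
        else:
            se = float(dwells.std(ddof=1) / np.sqrt(dwells.size)) if dwells.size > 1 else float("nan")
            paths[p] = PathStat(float(dwells.mean()), se, int(dwells.size))
    return MstEstimate(paths=paths, n_censored=censored)


DEFAULT_ENTRY_AGE_EDGES = (0.0, 40.0, 50.0, 60.0, 70.0, 200.0)


def progression_proportions(
    log: PairedEventLog,
    universe: str = "unscreened",
    birth_cohort: int = 1930,
    entry_age_edges=DEFAULT_ENTRY_AGE_EDGES,
) -> pd.DataFrame:
    """Exit-path proportions by age at entry into the screen-detectable state.

    Returns one row per entry-age group with columns P1/P2/P3 (summing
    to 1 over resolved exits), the number of resolved exits, and the
    separately reported death-censored fraction.
    """
    histories = [h for h in log.histories(universe) if h.birth_year == birth_cohort]
    if not histories:
        raise InputError(f"birth cohort {birth_cohort} absent from the log")
    by_path, _ = _screen_detectable_episodes(histories)
    edges = np.asarray(entry_age_edges, dtype=float)
    labels = [f"{int(a)}-{int(b) - 1}" for a, b in zip(edges, edges[1:])]

    # re-walk per history to also bin censored episodes by entry age
    resolved = {lab: {p: 0 for p in st.PATHS} for lab in labels}
    censored = {lab: 0 for lab in labels}
    for h in histories:
        for i, ev in enumerate(h.events):
            if ev.state != st.DCIS_SCREEN_DETECTABLE:
                continue
            gi = int(np.searchsorted(edges, ev.age, side="right")) - 1
            if gi < 0 or gi >= len(labels):
                break
            lab = labels[gi]
            nxt = h.events[i + 1] if i + 1 < len(h.events) else None
            if nxt is not None and nxt.state in _EXIT_TO_PATH:
                resolved[lab][_EXIT_TO_PATH[nxt.state]] += 1
            else:
                censored[lab] += 1
            break

    rows = []
    for lab in labels:
        n_res = sum(resolved[lab].values())
        n_cen = censored[lab]
        if n_res + n_cen == 0:
            continue
        props = {
            p: (resolved[lab][p] / n_res if n_res > 0 else float("nan")) for p in st.PATHS
        }
        rows.append(
            {
                "entry_age_group": lab,
                **props,
                "n_resolved": n_res,
                "censored_fraction": n_cen / (n_res + n_cen),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DiagnosisAccounting:
    screen_detected: int
    clinically_detected: int
    overdiagnosed: int

    @property
    def percentage(self) -> float:
        denom = self.screen_detected + self.clinically_detected
        return 100.0 * self.overdiagnosed / denom if denom > 0 else 0.0


@dataclass
class OverdiagnosisReport:
    """Counterfactual accounting of screen-detected cases.

    A screen-detected DCIS case is overdiagnosed iff the same woman's
    unscreened universe shows neither clinical DCIS nor clinical IBC
    before other-cause death; a screen-detected IBC case iff it shows no
    clinical IBC.  Percentages divide overdiagnosed cases by all
    screen-detected plus clinically detected cases.
    """

    dcis: DiagnosisAccounting
    ibc: DiagnosisAccounting
    combined: DiagnosisAccounting
    by_age_group: pd.DataFrame = field(default_factory=pd.DataFrame)
    by_year: pd.DataFrame = field(default_factory=pd.DataFrame)


def _is_overdiagnosed(unscreened: LifeHistory, detected_state: str) -> bool:
    if detected_state == st.SCREEN_DETECTED_DCIS:
        return not (unscreened.has_state(st.CLINICAL_DCIS) or unscreened.has_state(st.IBC_CLINICAL))
    if detected_state == st.SCREEN_DETECTED_IBC:
        return not unscreened.has_state(st.IBC_CLINICAL)
    raise InputError(f"not a screen-detection state: {detected_state}")


def compute_overdiagnosis(log: PairedEventLog) -> OverdiagnosisReport:
    """Counterfactual overdiagnosis from paired universes."""
    counts = {
        d: {"screen": 0, "clinical": 0, "over": 0} for d in (st.DIAG_DCIS, st.DIAG_IBC)
    }
    strata_age: dict[tuple[str, str], dict[str, int]] = {}
    strata_year: dict[tuple[str, int], dict[str, int]] = {}

    for pair in log.pairs:
        if pair.unscreened.woman_id != pair.screened.woman_id:
            raise ConsistencyError(f"unpaired woman_id in pair {pair.woman_id}")
        ev = first_diagnosis(pair.screened)
        if ev is None:
            continue
        diag, mode = st.DIAGNOSIS_EVENTS[ev.state]
        over = False
        if mode == "screen":
            over = _is_overdiagnosed(pair.unscreened, ev.state)
        counts[diag][mode] += 1
        counts[diag]["over"] += int(over)

        group = st.age_group_label(ev.age)
        if group is not None:
            cell = strata_age.setdefault((diag, group), {"screen": 0, "clinical": 0, "over": 0})
            cell[mode] += 1
            cell["over"] += int(over)
        ycell = strata_year.setdefault(
            (diag, int(pair.birth_year + ev.age)), {"screen": 0, "clinical": 0, "over": 0}
        )
        ycell[mode] += 1
        ycell["over"] += int(over)

    def acct(c) -> DiagnosisAccounting:
        return DiagnosisAccounting(c["screen"], c["clinical"], c["over"])

    dcis = acct(counts[st.DIAG_DCIS])
    ibc = acct(counts[st.DIAG_IBC])
    combined = DiagnosisAccounting(
        dcis.screen_detected + ibc.screen_detected,
        dcis.clinically_detected + ibc.clinically_detected,
        dcis.overdiagnosed + ibc.overdiagnosed,
    )

    def strata_frame(strata: dict, key_name: str) -> pd.DataFrame:
        rows = []
        for (diag, key), c in sorted(strata.items()):
            a = acct(c)
            rows.append(
                {
                    "diagnosis": diag,
                    key_name: key,
                    "screen_detected": a.screen_detected,
                    "clinically_detected": a.clinically_detected,
                    "overdiagnosed": a.overdiagnosed,
                    "percentage": a.percentage,
                }
            )
        return pd.DataFrame(rows)

    return OverdiagnosisReport(
        dcis=dcis,
        ibc=ibc,
        combined=combined,
        by_age_group=strata_frame(strata_age, "age_group"),
        by_year=strata_frame(strata_year, "year"),
    )
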