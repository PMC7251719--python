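"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: cohort life
tables (Gompertz-shaped), dissemination tables (logistic uptake ramp
that plateaus after 2010), standard-population weights, and
SEER-like observed incidence produced by running the simulator at the
scenario's true parameters and adding Poisson sampling noise.  Each
bundled scenario records every true value in a provenance manifest so
round-trip recovery tests have an exact target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .cohort_sim import LifeTable, PopulationSpec, simulate_population
from .errors import InvalidParameterError
from .natural_history import NaturalHistoryParams, PiecewiseConstantHazard, SubmodelConfig
from .outcomes import IncidenceTable, compute_incidence, equal_standard_weights
from .screening import DisseminationSchedule, default_sensitivity_schedule
from . import states as st

__all__ = [
    "SyntheticScenario",
    "MODEL_D_MST",
    "make_life_table",
    "make_dissemination",
    "make_standard_weights",
    "make_observed_incidence",
    "default_onset_hazard",
    "scenario",
    "write_scenario",
]

#: Path-specific mean sojourn time inputs (years) per submodel:
#: (to preclinical IBC, to clinical DCIS, to regression; None = path closed).
MODEL_D_MST = {
    "1a": (2.5, 2.5, None),
    "1b": (1.5, 1.5, 1.5),
    "2a": (0.7, 1.9, None),
    "2b": (0.5, 1.9, 1.5),
    "3a": (0.4, 1.9, None),
    "3b": (0.2, 1.9, 1.5),
}

#: Declared synthetic exit-path probabilities (p1, p2, p3).
DEFAULT_PATH_PROBS = {False: (0.80, 0.20, 0.0), True: (0.50, 0.20, 0.30)}

DEFAULT_COHORTS = tuple(range(1890, 1997))
OBSERVED_YEARS = tuple(range(1975, 2016))


def make_life_table(
    gompertz_scale: float = 6e-5,
    gompertz_shape: float = 0.088,
    cohorts=DEFAULT_COHORTS,
    max_age: int = 110,
    cohort_improvement: float = 0.0,
) -> pd.DataFrame:
    """Gompertz-shaped annual other-cause death probabilities.

    The final age carries probability 1 so every woman dies within the
    table.  ``cohort_improvement`` optionally lowers mortality by a
    log-linear factor per birth year after 1890.
    """
    if gompertz_scale <= 0 or gompertz_shape <= 0:
        raise InvalidParameterError("Gompertz parameters must be positive")
    ages = np.arange(max_age)
    rows = []
    for by in cohorts:
        factor = np.exp(-cohort_improvement * (by - 1890))
        q = np.minimum(gompertz_scale * factor * np.exp(gompertz_shape * ages), 1.0)
        if np.any(q > 1.0) or np.any(q < 0):
            raise InvalidParameterError("death probabilities overflow [0, 1]")
        q[-1] = 1.0
        rows.append(pd.DataFrame({"birth_year": by, "age": ages, "annual_other_cause_death_prob": q}))
    return pd.concat(rows, ignore_index=True)


def make_dissemination(
    plateau: float = 0.8,
    midpoint: float = 1990.0,
    steepness: float = 0.25,
    cohorts=DEFAULT_COHORTS,
    years=tuple(range(1975, 2061)),
    interval_years: float = 2.0,
) -> pd.DataFrame:
    """Logistic ever-screener uptake ramp, held constant after 2010."""
    if not 0 <= plateau <= 1:
        raise InvalidParameterError("plateau must lie in [0, 1]")
    years = np.asarray(sorted(years), dtype=int)
    capped = np.minimum(years, 2010)
    probs = plateau * special.expit(steepness * (capped - midpoint))
    rows = []
    for by in cohorts:
        rows.append(
            pd.DataFrame(
                {
                    "birth_year": by,
                    "calendar_year": years,
                    "start_probability": probs,
                    "interval_years": interval_years,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def make_standard_weights() -> pd.DataFrame:
    """Equal standard-population weights over the ten groups 30-79."""
    w = equal_standard_weights()
    return pd.DataFrame({"age_group": list(w), "weight": list(w.values())})


def default_onset_hazard(
    scale: float = 1.0, cohort_log_slope: float = 0.005
) -> PiecewiseConstantHazard:
    """Age-increasing onset hazard in 5-year bands with a cohort trend.

    Zero below age 30, rising to a plateau around age 60-70.  Lifetime
    cumulative hazard is a few percent at scale 1.
    """
    band_starts = [0.0] + [float(a) for a in range(30, 80, 5)]
    band_values = [0.0, 2e-4, 4e-4, 7e-4, 1.0e-3, 1.3e-3, 1.5e-3, 1.6e-3, 1.6e-3, 1.5e-3, 1.3e-3]
    return PiecewiseConstantHazard(
        band_starts,
        [v * scale for v in band_values],
        cohort_log_slope=cohort_log_slope,
        cohort_ref_year=1950.0,
    )


@dataclass
class SyntheticScenario:
    """A fully specified synthetic world with declared ground truth."""

    name: str
    config: SubmodelConfig
    params: NaturalHistoryParams
    seed: int
    onset_scale: float = 1.0
    cohorts: tuple = DEFAULT_COHORTS
    gompertz_scale: float = 6e-5
    gompertz_shape: float = 0.088
    dissem_plateau: float = 0.8
    dissem_midpoint: float = 1990.0
    dissem_steepness: float = 0.25
    screen_interval_years: float = 2.0

    def life_table(self) -> LifeTable:
        return LifeTable(
            make_life_table(self.gompertz_scale, self.gompertz_shape, self.cohorts)
        )

    def dissemination(self) -> DisseminationSchedule:
        return DisseminationSchedule(
            make_dissemination(
                self.dissem_plateau,
                self.dissem_midpoint,
                self.dissem_steepness,
                self.cohorts,
                interval_years=self.screen_interval_years,
            )
        )

    def population_spec(self, n_women: int, seed: int | None = None) -> PopulationSpec:
        return PopulationSpec(
            config=self.config,
            params=self.params,
            life_table=self.life_table(),
            sensitivity=default_sensitivity_schedule(),
            dissemination=self.dissemination(),
            cohorts=self.cohorts,
            n_women=n_women,
            seed=self.seed if seed is None else seed,
        )

    def manifest(self) -> dict:
        p = self.params
        return {
            "name": self.name,
            "seed": self.seed,
            "submodel": asdict(self.config),
            "true_params": {
                "p1": p.p1,
                "p2": p.p2,
                "p3": p.p3,
                "mst1": p.mst1,
                "mst2": p.mst2,
                "mst3": p.mst3,
                "undetectable_mean_dwell": p.undetectable_mean_dwell,
                "undetectable_direct_to_ibc_frac": p.undetectable_direct_to_ibc_frac,
                "ibc_preclinical_mean_dwell": p.ibc_preclinical_mean_dwell,
                "onset_breaks": p.onset_hazard.breaks,
                "onset_values": p.onset_hazard.values,
                "onset_cohort_log_slope": p.onset_hazard.cohort_log_slope,
                "onset_cohort_ref_year": p.onset_hazard.cohort_ref_year,
            },
            "life_table": {
                "gompertz_scale": self.gompertz_scale,
                "gompertz_shape": self.gompertz_shape,
            },
            "dissemination": {
                "plateau": self.dissem_plateau,
                "midpoint": self.dissem_midpoint,
                "steepness": self.dissem_steepness,
                "interval_years": self.screen_interval_years,
            },
            "cohorts": [int(self.cohorts[0]), int(self.cohorts[-1])],
        }


def scenario(
    name: str,
    seed: int = 0,
    onset_scale: float = 1.0,
    cohorts=DEFAULT_COHORTS,
) -> SyntheticScenario:
    """One of the six bundled scenarios (1a..3b) with declared truth."""
    config = SubmodelConfig.from_id(name)
    mst1, mst2, mst3 = MODEL_D_MST[config.submodel_id]
    p1, p2, p3 = DEFAULT_PATH_PROBS[config.regression_allowed]
    params = NaturalHistoryParams(
        onset_hazard=default_onset_hazard(onset_scale),
        undetectable_mean_dwell=2.0,
        undetectable_direct_to_ibc_frac=0.5,
        p1=p1,
        p2=p2,
        p3=p3,
        mst1=mst1,
        mst2=mst2,
        mst3=mst3,
        ibc_preclinical_mean_dwell=2.0,
    )
    return SyntheticScenario(
        name=config.submodel_id,
        config=config,
        params=params,
        seed=seed,
        onset_scale=onset_scale,
        cohorts=tuple(cohorts),
    )


def make_observed_incidence(
    scn: SyntheticScenario,
    n_sim: int,
    cell_population: float = 200_000.0,
    years=OBSERVED_YEARS,
) -> tuple[pd.DataFrame, IncidenceTable, IncidenceTable]:
    """SEER-like observed incidence from a run at the true parameters.

    Simulates ``n_sim`` women, pools detection modes per (year, age
    group, diagnosis), and perturbs each cell with Poisson noise at a
    declared population size.  Returns the observed CSV-shaped frame,
    the observed table (with age-adjusted rates), and the noise-free
    truth table.
    """
    log = simulate_population(scn.population_spec(n_sim))
    truth = compute_incidence(log, "screened")
    cells = truth.cells
    cells = cells[cells["year"].isin(list(years))]
    pooled = (
        cells.groupby(["year", "age_group", "diagnosis"], as_index=False)[["count", "women_years"]]
        .agg({"count": "sum", "women_years": "first"})
    )
    rate = np.where(
        pooled["women_years"] > 0, 1e5 * pooled["count"] / pooled["women_years"], 0.0
    )
    rng = np.random.default_rng([scn.seed, 104729])  # noise stream distinct from simulation
    lam = rate / 1e5 * cell_population
    noisy_counts = rng.poisson(lam)
    observed = pooled[["year", "age_group", "diagnosis"]].copy()
    observed["rate_per_100k"] = 1e5 * noisy_counts / cell_population
    observed = observed.sort_values(["year", "diagnosis", "age_group"]).reset_index(drop=True)
    table = IncidenceTable.from_observed_frame(observed, truth.weights)
    return observed, table, truth


def write_scenario(scn: SyntheticScenario, outdir, n_sim: int = 20_000) -> dict:
    """Write the four input CSVs plus a provenance manifest to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    life = make_life_table(scn.gompertz_scale, scn.gompertz_shape, scn.cohorts)
    dissem = make_dissemination(
        scn.dissem_plateau,
        scn.dissem_midpoint,
        scn.dissem_steepness,
        scn.cohorts,
        interval_years=scn.screen_interval_years,
    )
    weights = make_standard_weights()
    observed, _, _ = make_observed_incidence(scn, n_sim)
    life.to_csv(outdir / "life_table.csv", index=False)
    dissem.to_csv(outdir / "dissemination.csv", index=False)
    weights.to_csv(outdir / "standard_weights.csv", index=False)
    observed.to_csv(outdir / "observed_incidence.csv", index=False)
    manifest = scn.manifest()
    manifest["n_sim"] = n_sim
    manifest["files"] = [
        "life_table.csv",
        "dissemination.csv",
        "standard_weights.csv",
        "observed_incidence.csv",
    ]
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
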