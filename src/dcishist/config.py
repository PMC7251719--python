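"""YAML configuration for simulation runs.

A run config names the submodel, the natural-history parameters, the
sensitivity periods, and the paths of the life-table and dissemination
CSVs (relative paths resolve against the config file's directory).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml

from .cohort_sim import LifeTable, PopulationSpec
from .errors import InputError
from .natural_history import NaturalHistoryParams, PiecewiseConstantHazard, SubmodelConfig
from .screening import DisseminationSchedule, SensitivitySchedule, default_sensitivity_schedule

__all__ = ["load_spec", "dump_config", "config_hash"]


def _onset_from_dict(d: dict) -> PiecewiseConstantHazard:
    return PiecewiseConstantHazard(
        d["breaks"],
        d["values"],
        cohort_log_slope=d.get("cohort_log_slope", 0.0),
        cohort_ref_year=d.get("cohort_ref_year", 1950.0),
    )


def _sensitivity_from_list(items) -> SensitivitySchedule:
    periods = tuple(
        (float(it["start_year"]), float(it["dcis_sensitivity"]), float(it.get("ibc_sensitivity", 0.85)))
        for it in items
    )
    return SensitivitySchedule(periods)


def load_spec(path, n_women: int, seed: int) -> PopulationSpec:
    """Build a PopulationSpec from a YAML run config."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InputError("config must be a mapping")
    base = path.parent

    config = SubmodelConfig.from_id(cfg["submodel"])
    if "frac_to_screen_detectable" in cfg.get("params", {}):
        from dataclasses import replace

        config = replace(
            config, frac_to_screen_detectable=float(cfg["params"]["frac_to_screen_detectable"])
        )
    p = cfg["params"]
    params = NaturalHistoryParams(
        onset_hazard=_onset_from_dict(p["onset"]),
        undetectable_mean_dwell=float(p["undetectable_mean_dwell"]),
        undetectable_direct_to_ibc_frac=float(p["undetectable_direct_to_ibc_frac"]),
        p1=float(p["p1"]),
        p2=float(p["p2"]),
        p3=float(p["p3"]),
        mst1=float(p["mst1"]),
        mst2=float(p["mst2"]),
        mst3=None if p.get("mst3") is None else float(p["mst3"]),
        ibc_preclinical_mean_dwell=float(p["ibc_preclinical_mean_dwell"]),
    )
    sensitivity = (
        _sensitivity_from_list(cfg["sensitivity"])
        if "sensitivity" in cfg
        else default_sensitivity_schedule()
    )
    life_table = LifeTable.from_csv(base / cfg["life_table_csv"])
    dissemination = DisseminationSchedule.from_csv(base / cfg["dissemination_csv"])
    cohorts_cfg = cfg.get("cohorts", {"start": 1890, "end": 1996})
    cohorts = tuple(range(int(cohorts_cfg["start"]), int(cohorts_cfg["end"]) + 1))
    return PopulationSpec(
        config=config,
        params=params,
        life_table=life_table,
        sensitivity=sensitivity,
        dissemination=dissemination,
        cohorts=cohorts,
        n_women=n_women,
        seed=seed,
    )


def dump_config(scn, outdir, life_table_csv="life_table.csv", dissemination_csv="dissemination.csv") -> Path:
    """Write a run config YAML for a synthetic scenario's true parameters."""
    p = scn.params
    cfg = {
        "submodel": scn.config.submodel_id,
        "params": {
            "frac_to_screen_detectable": scn.config.frac_to_screen_detectable,
            "p1": p.p1,
            "p2": p.p2,
            "p3": p.p3,
            "mst1": p.mst1,
            "mst2": p.mst2,
            "mst3": p.mst3,
            "undetectable_mean_dwell": p.undetectable_mean_dwell,
            "undetectable_direct_to_ibc_frac": p.undetectable_direct_to_ibc_frac,
            "ibc_preclinical_mean_dwell": p.ibc_preclinical_mean_dwell,
            "onset": {
                "breaks": list(p.onset_hazard.breaks),
                "values": list(p.onset_hazard.values),
                "cohort_log_slope": p.onset_hazard.cohort_log_slope,
                "cohort_ref_year": p.onset_hazard.cohort_ref_year,
            },
        },
        "sensitivity": [
            {"start_year": s, "dcis_sensitivity": d, "ibc_sensitivity": i}
            for s, d, i in default_sensitivity_schedule().periods
        ],
        "life_table_csv": life_table_csv,
        "dissemination_csv": dissemination_csv,
        "cohorts": {"start": int(scn.cohorts[0]), "end": int(scn.cohorts[-1])},
    }
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = outdir / "config.yaml"
    with open(out, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return out


def config_hash(path) -> str:
    """SHA-256 of the canonicalized config file contents."""
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()
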