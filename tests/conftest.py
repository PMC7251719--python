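"""Shared fixtures: small parameter sets, synthetic worlds, and one large
session-scoped unscreened log reused by the statistical recovery tests."""

import numpy as np
import pandas as pd
import pytest

from dcishist.cohort_sim import LifeTable, PairedEventLog, WomanPair
from dcishist.natural_history import (
    NaturalHistoryParams,
    PiecewiseConstantHazard,
    SubmodelConfig,
    simulate_lesion,
)
from dcishist.screening import DisseminationSchedule


def make_params(
    p=(0.5, 0.3, 0.2),
    msts=(2.5, 1.9, 1.5),
    onset=None,
    undetectable_mean_dwell=2.0,
    direct_frac=0.5,
    ibc_dwell=2.0,
):
    return NaturalHistoryParams(
        onset_hazard=onset or PiecewiseConstantHazard.constant(0.01),
        undetectable_mean_dwell=undetectable_mean_dwell,
        undetectable_direct_to_ibc_frac=direct_frac,
        p1=p[0],
        p2=p[1],
        p3=p[2],
        mst1=msts[0],
        mst2=msts[1],
        mst3=msts[2],
        ibc_preclinical_mean_dwell=ibc_dwell,
    )


def fast_onset_params(**kw):
    """Onset almost immediately after birth; useful for uncensored dwell studies."""
    return make_params(onset=PiecewiseConstantHazard.constant(10.0), **kw)


def simulate_unscreened_log(config, params, n, seed, birth_year=1930, death_age=150.0):
    """n unscreened lesions wrapped as a paired log (screened = unscreened)."""
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        hist = simulate_lesion(config, params, birth_year, death_age, rng, woman_id=i)
        pairs.append(WomanPair(i, birth_year, death_age, hist, hist))
    return PairedEventLog(pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config_2b():
    return SubmodelConfig.from_id("2b")


@pytest.fixture
def config_1a():
    return SubmodelConfig.from_id("1a")


@pytest.fixture
def params_2b():
    return make_params()


@pytest.fixture
def params_1a():
    return make_params(p=(0.8, 0.2, 0.0), msts=(2.5, 2.5, None))


@pytest.fixture
def uniform_life_table():
    """Everyone dies exactly in the year [85, 86) (prob 1 at age 85)."""
    ages = np.arange(86)
    q = np.zeros(86)
    q[85] = 1.0
    rows = []
    for by in range(1890, 1997):
        rows.append(
            pd.DataFrame({"birth_year": by, "age": ages, "annual_other_cause_death_prob": q})
        )
    return LifeTable(pd.concat(rows, ignore_index=True))


@pytest.fixture
def flat_dissemination():
    """Constant 100% uptake from 1975, biennial screens from age 40."""
    years = np.arange(1975, 2061)
    rows = []
    for by in range(1890, 1997):
        rows.append(
            pd.DataFrame(
                {
                    "birth_year": by,
                    "calendar_year": years,
                    "start_probability": 1.0,
                    "interval_years": 2.0,
                }
            )
        )
    return DisseminationSchedule(pd.concat(rows, ignore_index=True))


@pytest.fixture(scope="session")
def big_unscreened_log_2b():
    """10^5 unscreened lesions under p=(0.5,0.3,0.2), msts=(2.5,1.9,1.5)."""
    config = SubmodelConfig.from_id("2b")
    params = fast_onset_params()
    return simulate_unscreened_log(config, params, n=100_000, seed=777)
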