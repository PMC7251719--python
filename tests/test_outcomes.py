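import math

import numpy as np
import pandas as pd
import pytest

from dcishist import states as st
from dcishist.cohort_sim import PairedEventLog, PopulationSpec, WomanPair, simulate_population
from dcishist.errors import ConsistencyError, InputError
from dcishist.natural_history import Event, LifeHistory, SubmodelConfig
from dcishist.outcomes import (
    compute_incidence,
    compute_overdiagnosis,
    equal_standard_weights,
    estimate_mst,
    first_diagnosis,
    progression_proportions,
)
from dcishist.screening import default_sensitivity_schedule

from conftest import make_params, simulate_unscreened_log


def pair_from_events(woman_id, birth_year, death_age, unscreened_events, screened_events=None):
    uns = LifeHistory(woman_id, birth_year, death_age, unscreened_events)
    scr = (
        uns
        if screened_events is None
        else LifeHistory(woman_id, birth_year, death_age, screened_events)
    )
    return WomanPair(woman_id, birth_year, death_age, uns, scr)


@pytest.fixture
def screened_scenario_log(uniform_life_table, flat_dissemination):
    spec = PopulationSpec(
        config=SubmodelConfig.from_id("2b"),
        params=make_params(onset=None),
        life_table=uniform_life_table,
        sensitivity=default_sensitivity_schedule(),
        dissemination=flat_dissemination,
        cohorts=tuple(range(1920, 1961)),
        n_women=20_000,
        seed=7,
    )
    return simulate_population(spec)


class TestIncidence:
    def test_rate_arithmetic(self):
        # 1,000 women alive exactly [0, 31); one clinical DCIS diagnosis
        pairs = []
        for i in range(999):
            pairs.append(pair_from_events(i, 1940, 31.0, [Event(st.DEATH_OTHER, 31.0)]))
        pairs.append(
            pair_from_events(
                999,
                1940,
                31.0,
                [Event(st.CLINICAL_DCIS, 31.0 - 1e-9), Event(st.DEATH_OTHER, 31.0)],
            )
        )
        table = compute_incidence(PairedEventLog(pairs), "unscreened")
        cell = table.cells.query(
            "year == 1970 and age_group == '30-34' and diagnosis == 'DCIS' and mode == 'clinical'"
        )
        assert cell["count"].item() == 1
        assert cell["women_years"].item() == pytest.approx(1000.0)
        assert cell["rate_per_100k"].item() == pytest.approx(100.0)

    def test_unscreened_universe_no_screen_mode(self, screened_scenario_log):
        table = compute_incidence(screened_scenario_log, "unscreened")
        assert table.cells.query("mode == 'screen'")["count"].sum() == 0

    def test_tally_oracle(self, screened_scenario_log):
        # independent brute-force tally of the raw event frame
        table = compute_incidence(screened_scenario_log, "screened")
        events = screened_scenario_log.to_events()
        events = events[events["universe"] == "screened"]
        diag = events[events["state"].isin(st.DIAGNOSIS_EVENTS)]
        diag = diag.sort_values("age").groupby("woman_id").first().reset_index()
        diag = diag[(diag["age"] >= 30) & (diag["age"] < 80)]
        for state, (d, m) in st.DIAGNOSIS_EVENTS.items():
            sub = diag[diag["state"] == state]
            expected = len(sub)
            got = table.cells.query("diagnosis == @d and mode == @m")["count"].sum()
            assert got == expected

    def test_age_adjusted_is_weighted_sum(self, screened_scenario_log):
        table = compute_incidence(screened_scenario_log, "screened")
        year = 2000
        w = equal_standard_weights()
        sub = table.cells.query("year == @year and diagnosis == 'DCIS'")
        pooled = sub.groupby("age_group").agg({"count": "sum", "women_years": "first"})
        expected = sum(
            w[g] * 1e5 * row["count"] / row["women_years"] for g, row in pooled.iterrows()
        )
        got = table.age_adjusted_rate(st.DIAG_DCIS).loc[year]
        assert got == pytest.approx(expected)

    def test_bad_weights_rejected(self, screened_scenario_log):
        w = equal_standard_weights()
        w["30-34"] = 0.5
        with pytest.raises(InputError):
            compute_incidence(screened_scenario_log, "screened", weights=w)

    def test_empty_log_empty_table(self):
        table = compute_incidence(PairedEventLog([]), "unscreened")
        assert table.cells.empty and table.age_adjusted.empty


class TestMst:
    def test_regression_prohibited_p3_absent(self):
        config = SubmodelConfig.from_id("1a")
        params = make_params(p=(0.8, 0.2, 0.0), msts=(2.5, 2.5, None))
        from conftest import fast_onset_params  # noqa: F401

        log = simulate_unscreened_log(config, params, n=5000, seed=3)
        est = estimate_mst(log)
        assert est.paths[st.PATH_P3] is None

    def test_pooled_mean_all_one(self):
        config = SubmodelConfig.from_id("2b")
        params = make_params(msts=(1.0, 1.0, 1.0))
        from dcishist.natural_history import PiecewiseConstantHazard

        params = make_params(
            msts=(1.0, 1.0, 1.0), onset=PiecewiseConstantHazard.constant(10.0)
        )
        log = simulate_unscreened_log(config, params, n=50_000, seed=4)
        est = estimate_mst(log)
        pooled = est.pooled_mean()
        n = sum(s.n for s in est.paths.values() if s)
        assert abs(pooled - 1.0) < 3 * 1.0 / math.sqrt(n)

    def test_censored_episodes_excluded(self):
        # woman dies in-state: no dwell contribution, counted as censored
        pairs = [
            pair_from_events(
                0,
                1940,
                70.0,
                [
                    Event(st.DCIS_UNDETECTABLE, 60.0),
                    Event(st.DCIS_SCREEN_DETECTABLE, 65.0),
                    Event(st.DEATH_OTHER, 70.0),
                ],
            )
        ]
        est = estimate_mst(PairedEventLog(pairs))
        assert est.n_censored == 1
        assert all(v is None for v in est.paths.values())


class TestProgressionProportions:
    def test_pure_p1(self):
        config = SubmodelConfig.from_id("2b")
        from dcishist.natural_history import PiecewiseConstantHazard

        params = make_params(
            p=(1.0, 0.0, 0.0), onset=PiecewiseConstantHazard.constant(5.0)
        )
        log = simulate_unscreened_log(config, params, n=3000, seed=5)
        props = progression_proportions(log, birth_cohort=1930)
        assert (props[st.PATH_P1] == 1.0).all()

    def test_paper_lower_bound_64_36(self):
        config = SubmodelConfig.from_id("2a")
        from dcishist.natural_history import PiecewiseConstantHazard

        params = make_params(
            p=(0.64, 0.36, 0.0),
            msts=(0.7, 1.9, None),
            onset=PiecewiseConstantHazard.constant(10.0),
        )
        log = simulate_unscreened_log(config, params, n=100_000, seed=6)
        props = progression_proportions(log, birth_cohort=1930)
        n = props["n_resolved"].sum()
        p1 = (props[st.PATH_P1] * props["n_resolved"]).sum() / n
        p2 = (props[st.PATH_P2] * props["n_resolved"]).sum() / n
        assert abs(p1 - 0.64) < 3 * math.sqrt(0.64 * 0.36 / n)
        assert abs(p2 - 0.36) < 3 * math.sqrt(0.64 * 0.36 / n)

    def test_tally_oracle(self, big_unscreened_log_2b):
        props = progression_proportions(big_unscreened_log_2b, birth_cohort=1930)
        # brute-force path tally over all entry ages
        tally = {p: 0 for p in st.PATHS}
        for hist in big_unscreened_log_2b.histories("unscreened"):
            win = hist.interval_of(st.DCIS_SCREEN_DETECTABLE)
            if win is None:
                continue
            nxt = hist.state_at(win[1])
            for path, state in (
                (st.PATH_P1, st.IBC_PRECLINICAL),
                (st.PATH_P2, st.CLINICAL_DCIS),
                (st.PATH_P3, st.REGRESSED),
            ):
                if nxt == state:
                    tally[path] += 1
        n = props["n_resolved"].sum()
        assert n == sum(tally.values())
        for path in st.PATHS:
            got = (props[path] * props["n_resolved"]).sum() / n
            assert got == pytest.approx(tally[path] / n)

    def test_missing_cohort_errors(self, big_unscreened_log_2b):
        with pytest.raises(InputError):
            progression_proportions(big_unscreened_log_2b, birth_cohort=1850)

    def test_proportions_sum_to_one(self, big_unscreened_log_2b):
        props = progression_proportions(big_unscreened_log_2b, birth_cohort=1930)
        sums = props[list(st.PATHS)].sum(axis=1)
        assert np.allclose(sums[props["n_resolved"] > 0], 1.0)


class TestOverdiagnosis:
    def test_zero_screening_zero_percentage(self, big_unscreened_log_2b):
        report = compute_overdiagnosis(big_unscreened_log_2b)
        assert report.dcis.screen_detected == 0
        assert report.dcis.overdiagnosed == 0

    def test_zero_denominator_guarded(self):
        report = compute_overdiagnosis(PairedEventLog([]))
        assert report.dcis.percentage == 0.0
        assert report.combined.percentage == 0.0

    def test_regressing_lesion_always_overdiagnosed(self):
        unscreened = [
            Event(st.DCIS_UNDETECTABLE, 58.0),
            Event(st.DCIS_SCREEN_DETECTABLE, 60.0),
            Event(st.REGRESSED, 62.0),
            Event(st.DEATH_OTHER, 85.0),
        ]
        screened = [
            Event(st.DCIS_UNDETECTABLE, 58.0),
            Event(st.DCIS_SCREEN_DETECTABLE, 60.0),
            Event(st.SCREEN_DETECTED_DCIS, 61.0),
            Event(st.DEATH_OTHER, 85.0),
        ]
        log = PairedEventLog([pair_from_events(0, 1950, 85.0, unscreened, screened)])
        report = compute_overdiagnosis(log)
        assert report.dcis.overdiagnosed == 1
        assert report.dcis.percentage == 100.0

    def test_progressing_lesion_not_overdiagnosed(self):
        unscreened = [
            Event(st.DCIS_UNDETECTABLE, 58.0),
            Event(st.DCIS_SCREEN_DETECTABLE, 60.0),
            Event(st.CLINICAL_DCIS, 62.0),
            Event(st.DEATH_OTHER, 85.0),
        ]
        screened = [
            Event(st.DCIS_UNDETECTABLE, 58.0),
            Event(st.DCIS_SCREEN_DETECTABLE, 60.0),
            Event(st.SCREEN_DETECTED_DCIS, 61.0),
            Event(st.DEATH_OTHER, 85.0),
        ]
        log = PairedEventLog([pair_from_events(0, 1950, 85.0, unscreened, screened)])
        report = compute_overdiagnosis(log)
        assert report.dcis.overdiagnosed == 0

    def test_unpaired_woman_errors(self):
        uns = LifeHistory(0, 1950, 85.0, [Event(st.CLINICAL_DCIS, 60.0), Event(st.DEATH_OTHER, 85.0)])
        scr = LifeHistory(1, 1950, 85.0, [Event(st.CLINICAL_DCIS, 60.0), Event(st.DEATH_OTHER, 85.0)])
        with pytest.raises(ConsistencyError):
            compute_overdiagnosis(PairedEventLog([WomanPair(0, 1950, 85.0, uns, scr)]))

    def test_denominator_conservation(self, uniform_life_table, flat_dissemination):
        spec = PopulationSpec(
            config=SubmodelConfig.from_id("2b"),
            params=make_params(),
            life_table=uniform_life_table,
            sensitivity=default_sensitivity_schedule(),
            dissemination=flat_dissemination,
            cohorts=tuple(range(1920, 1961)),
            n_women=10_000,
            seed=8,
        )
        log = simulate_population(spec)
        report = compute_overdiagnosis(log)
        total_events = sum(
            1 for h in log.histories("screened") if first_diagnosis(h) is not None
        )
        got = (
            report.combined.screen_detected + report.combined.clinically_detected
        )
        assert got == total_events
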