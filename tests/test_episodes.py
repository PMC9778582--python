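from __future__ import annotations

import dataclasses
from datetime import date, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bph_persistence import (
    StudyConfig,
    build_episodes,
    grace_period,
    select_cohort,
    spans_from_records,
    supply_duration,
    time_to_discontinuation,
)
from bph_persistence.cohort import CohortMember
from bph_persistence.episodes import LEVEL_CLASS, LEVEL_DRUG, SupplySpan
from bph_persistence.pipeline import build_observations
from bph_persistence.synthetic_data import (
    DrugProfile,
    SimulationParams,
    generate_dataset,
)

from conftest import make_record

D0 = date(2018, 4, 10)


def _spans(day_duration_pairs, key="tamsulosin"):
    return [
        SupplySpan(key=key, drug_name=key, start=D0 + timedelta(days=d), duration_days=dur)
        for d, dur in day_duration_pairs
    ]


def _member(index=D0, death=None, followup_days=365):
    return CohortMember(
        patient_id="P1",
        age_at_reference=70,
        age_group="70-79",
        young_old="old",
        index_date=index,
        followup_end=index + timedelta(days=followup_days),
        death_date=death,
        drugs_prescribed=frozenset({"tamsulosin"}),
        classes_prescribed=frozenset({"AB"}),
        n_fill_dates=2,
    )


class TestSupplyAndGrace:
    @pytest.mark.parametrize(
        "n_packages,ddd,expected",
        [(1, 30.0, 30.0), (2, 30.0, 60.0), (1, 28.0, 28.0)],
    )
    def test_supply_duration_is_packages_times_ddd(self, n_packages, ddd, expected):
        rec = make_record(n_packages=n_packages, ddd=ddd)
        assert supply_duration(rec) == expected

    @pytest.mark.parametrize(
        "duration,multiplier,expected",
        [(30.0, 1.5, 45.0), (28.0, 1.5, 42.0), (30.0, 1.0, 30.0)],
    )
    def test_grace_period_scales_supply(self, duration, multiplier, expected):
        assert grace_period(duration, multiplier) == expected

    def test_non_positive_multiplier_rejected(self):
        with pytest.raises(ValueError):
            grace_period(30.0, 0.0)


class TestBuildEpisodes:
    def test_refill_within_grace_continues_episode(self, config):
        eps = build_episodes(_spans([(0, 30), (40, 30)]), LEVEL_DRUG, config)
        assert len(eps) == 1
        assert eps[0].supply_end == D0 + timedelta(days=70)
        assert eps[0].n_dispensations == 2

    def test_refill_beyond_grace_breaks_episode(self, config):
        eps = build_episodes(_spans([(0, 30), (50, 30)]), LEVEL_DRUG, config)
        assert len(eps) == 2
        assert eps[0].supply_end == D0 + timedelta(days=30)
        assert eps[0].terminated_by == "gap"

    def test_early_refill_carries_over_supply(self, config):
        eps = build_episodes(_spans([(0, 30), (10, 30)]), LEVEL_DRUG, config)
        assert len(eps) == 1
        assert eps[0].supply_end == D0 + timedelta(days=60)

    def test_same_day_fills_merge_with_summed_duration(self, config):
        recs = [make_record(on=D0), make_record(on=D0)]
        spans = spans_from_records(recs, config, LEVEL_DRUG)
        assert len(spans) == 1
        assert spans[0].duration_days == 60.0

    def test_unsorted_input_is_an_error(self, config):
        spans = _spans([(40, 30), (0, 30)])
        with pytest.raises(ValueError, match="sorted"):
            build_episodes(spans, LEVEL_DRUG, config)

    def test_supply_end_anchor_option(self):
        cfg = StudyConfig(gap_anchor="supply_end")
        # gap of 40 from the fill is 10 past supply end; allowed slack is
        # (1.5 - 1) x 30 = 15 days beyond exhaustion
        assert len(build_episodes(_spans([(0, 30), (40, 30)]), LEVEL_DRUG, cfg)) == 1
        assert len(build_episodes(_spans([(0, 30), (50, 30)]), LEVEL_DRUG, cfg)) == 2

    def test_every_dispensation_belongs_to_exactly_one_episode(self, config):
        spans = _spans([(0, 30), (25, 30), (100, 30), (140, 30), (300, 30)])
        eps = build_episodes(spans, LEVEL_DRUG, config)
        assert sum(e.n_dispensations for e in eps) == len(spans)

    @settings(max_examples=60, derandomize=True)
    @given(
        gaps=st.lists(st.integers(1, 120), min_size=1, max_size=8),
    )
    def test_event_times_monotone_in_grace_multiplier(self, gaps):
        days, acc = [0], 0
        for g in gaps:
            acc += g
            days.append(acc)
        member = _member()
        prev_t, prev_e = -1, 2
        for m in (1.0, 1.25, 1.5, 2.0):
            cfg = StudyConfig(grace_multiplier=m)
            spans = _spans([(d, 30) for d in days])
            eps = build_episodes(
                spans, LEVEL_DRUG, cfg, followup_end=member.followup_end
            )
            obs = time_to_discontinuation(eps, member, cfg)
            assert obs.time_days >= prev_t
            assert obs.event <= prev_e
            prev_t, prev_e = obs.time_days, obs.event


class TestTimeToDiscontinuation:
    def test_single_fill_discontinues_at_supply_end(self, config):
        eps = build_episodes(
            _spans([(0, 30)]), LEVEL_DRUG, config, followup_end=_member().followup_end
        )
        obs = time_to_discontinuation(eps, _member(), config)
        assert (obs.time_days, obs.event) == (30, 1)

    def test_continuous_refills_censored_at_followup(self, config):
        spans = _spans([(30 * k, 30) for k in range(13)])  # through day 360
        eps = build_episodes(
            spans, LEVEL_DRUG, config, followup_end=_member().followup_end
        )
        obs = time_to_discontinuation(eps, _member(), config)
        assert (obs.time_days, obs.event) == (365, 0)

    def test_death_mid_episode_is_event_at_death(self, config):
        member = _member(death=D0 + timedelta(days=100))
        spans = _spans([(30 * k, 30) for k in range(5)])
        eps = build_episodes(
            spans,
            LEVEL_DRUG,
            config,
            death_date=member.death_date,
            followup_end=member.followup_end,
        )
        obs = time_to_discontinuation(eps, member, config)
        assert (obs.time_days, obs.event) == (100, 1)

    def test_supply_end_within_grace_of_horizon_is_censored(self, config):
        # supply ends day 330; 330 + 45 > 365 so the gap cannot be observed
        spans = _spans([(30 * k, 30) for k in range(11)])
        eps = build_episodes(
            spans, LEVEL_DRUG, config, followup_end=_member().followup_end
        )
        assert eps[0].terminated_by == "censored_alive"
        obs = time_to_discontinuation(eps, _member(), config)
        assert (obs.time_days, obs.event) == (365, 0)

    def test_no_episodes_is_an_error(self, config):
        with pytest.raises(ValueError):
            time_to_discontinuation([], _member(), config)


class TestAgainstGeneratorTruth:
    def _jitter_free_run(self, config, n=250, seed=17):
        profile = DrugProfile(
            drug_name="tamsulosin",
            atc_code="G04CA02",
            ddd_per_package=30.0,
            median_days=100.0,
            refill_jitter_sd=0.0,
        )
        params = SimulationParams(
            n_patients=n, seed=seed, switch_prob=0.0, class_mix=(1.0, 0.0, 0.0)
        )
        records, deaths, truth = generate_dataset(params, [profile], config)
        cohort, _ = select_cohort(records, deaths, config)
        obs = build_observations(records, cohort, config, LEVEL_DRUG)
        return truth, cohort, obs

    def test_drug_level_event_times_equal_truth(self, config):
        truth, cohort, obs = self._jitter_free_run(config)
        expected = truth.set_index("patient_id")
        eligible = {m.patient_id for m in cohort}
        checked = 0
        for o in obs["tamsulosin"]:
            row = expected.loc[o.patient_id]
            assert o.patient_id in eligible
            assert o.time_days == row["expected_time_days"]
            assert o.event == row["expected_event"]
            checked += 1
        assert checked == len(cohort)

    def test_class_time_at_least_index_drug_time(self, config):
        # equal supply durations: the class-level episode contains the index
        # drug's episode, so class persistence cannot be shorter
        params = SimulationParams(n_patients=200, seed=23)
        records, deaths, _ = generate_dataset(params, config=config)
        cohort, _ = select_cohort(records, deaths, config)
        drug_obs = build_observations(records, cohort, config, LEVEL_DRUG)
        class_obs = build_observations(records, cohort, config, LEVEL_CLASS)
        drug_by = {}
        for key, lst in drug_obs.items():
            for o in lst:
                drug_by[(o.patient_id, key)] = o
        by_patient = {}
        for r in records:
            by_patient.setdefault(r.patient_id, []).append(r)
        checked = 0
        for cls, lst in class_obs.items():
            for o in lst:
                member = next(m for m in cohort if m.patient_id == o.patient_id)
                fills = [
                    r
                    for r in by_patient[o.patient_id]
                    if config.drug_class(r.atc_code) == cls
                    and member.index_date <= r.dispensation_date < member.followup_end
                ]
                first = min(fills, key=lambda r: r.dispensation_date)
                index_drug = drug_by.get((o.patient_id, first.drug_name))
                if index_drug is not None:
                    assert o.time_days >= index_drug.time_days
                    checked += 1
        assert checked > 100
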