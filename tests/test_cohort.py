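from __future__ import annotations

import math
from datetime import date
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bph_persistence import (
    StudyConfig,
    assign_age_group,
    select_cohort,
    summarize_cohort,
    wilcoxon_rank_sum,
)
from bph_persistence.cohort import completed_years, percent, round_half_away
from bph_persistence.records_io import DeathRecord
from bph_persistence.synthetic_data import SimulationParams, generate_dataset

from conftest import make_record


class TestAgeGroups:
    def test_birthday_on_reference_date_counts_completed_year(self):
        assert completed_years(date(1948, 4, 1), date(2018, 4, 1)) == 70
        assert assign_age_group(date(1948, 4, 1), date(2018, 4, 1), (40, 50, 60, 70, 80, 90, 101)) == "70-79"

    def test_day_after_birthday_boundary(self):
        assert completed_years(date(1948, 4, 2), date(2018, 4, 1)) == 69
        assert assign_age_group(date(1948, 4, 2), date(2018, 4, 1), (40, 50, 60, 70, 80, 90, 101)) == "60-69"

    def test_oldest_group_reaches_one_hundred(self):
        assert assign_age_group(date(1923, 1, 1), date(2018, 4, 1), (40, 50, 60, 70, 80, 90, 101)) == "90-100"

    def test_age_beyond_last_edge_flagged(self):
        with pytest.warns(UserWarning):
            label = assign_age_group(date(1910, 1, 1), date(2018, 4, 1), (40, 50, 60, 70, 80, 90, 101))
        assert label == "out_of_range"

    def test_age_below_first_edge_is_error(self):
        with pytest.raises(ValueError):
            assign_age_group(date(2000, 1, 1), date(2018, 4, 1), (40, 50))


def _chronic_fills(pid, birth=date(1950, 1, 1), start=date(2018, 4, 10), n=4, **kw):
    out = [make_record(pid=pid, birth=birth, on=date(2015, 1, 1), drug="ramipril")]
    from datetime import timedelta

    for k in range(n):
        out.append(make_record(pid=pid, birth=birth, on=start + timedelta(days=30 * k), **kw))
    return out


class TestSelectCohort:
    def test_under_age_excluded_despite_many_fills(self, config):
        # 39 completed years at the reference date
        records = _chronic_fills("P1", birth=date(1978, 4, 2), n=5)
        cohort, ledger = select_cohort(records, [], config)
        assert not cohort
        assert ledger.status_by_patient["P1"] == "under_age"

    def test_forty_years_exactly_is_eligible(self, config):
        records = _chronic_fills("P1", birth=date(1978, 4, 1), n=5)
        cohort, _ = select_cohort(records, [], config)
        assert len(cohort) == 1

    def test_washout_fill_excludes_new_user(self, config):
        records = _chronic_fills("P1", start=date(2018, 5, 2), n=4)
        records.append(make_record(pid="P1", on=date(2018, 2, 10)))
        cohort, ledger = select_cohort(records, [], config)
        assert not cohort
        assert ledger.status_by_patient["P1"] == "washout_user"

    def test_single_prescription_is_occasional(self, config):
        records = _chronic_fills("P1", n=1)
        cohort, ledger = select_cohort(records, [], config)
        assert not cohort
        assert ledger.status_by_patient["P1"] == "occasional"

    def test_short_history_excluded(self, config):
        records = _chronic_fills("P1", n=4)[1:]  # drop the 2015 history record
        cohort, ledger = select_cohort(records, [], config)
        assert ledger.status_by_patient["P1"] == "short_history"

    def test_no_index_period_fill(self, config):
        records = _chronic_fills("P1", start=date(2018, 8, 1), n=4)
        _, ledger = select_cohort(records, [], config)
        assert ledger.status_by_patient["P1"] == "no_index_fill"

    def test_female_patients_counted_separately(self, config):
        records = _chronic_fills("P1", n=4)
        records += [
            make_record(pid="P2", sex="F", on=date(2018, 4, 12)),
            make_record(pid="P2", sex="F", on=date(2018, 5, 12)),
        ]
        cohort, ledger = select_cohort(records, [], config)
        assert len(cohort) == 1
        assert ledger.status_by_patient["P2"] == "not_male"

    def test_death_in_followup_retained(self, config):
        records = _chronic_fills("P1", n=4)
        deaths = [DeathRecord("P1", date(2018, 8, 1))]
        cohort, _ = select_cohort(records, deaths, config)
        assert len(cohort) == 1
        assert cohort[0].died_in_followup

    def test_empty_record_set_gives_empty_cohort_and_zeroed_ledger(self, config):
        cohort, ledger = select_cohort([], [], config)
        assert cohort == []
        assert ledger.n_patients == 0
        assert all(v == 0 for v in ledger.counts().values())

    def test_index_date_is_first_index_period_fill(self, config):
        records = _chronic_fills("P1", start=date(2018, 4, 20), n=4)
        cohort, _ = select_cohort(records, [], config)
        assert cohort[0].index_date == date(2018, 4, 20)

    def test_ledger_conservation_on_synthetic_data(self, config, small_dataset):
        _, (records, deaths, truth) = small_dataset
        _, ledger = select_cohort(records, deaths, config)
        study_patients = {
            r.patient_id for r in records if config.is_study_drug(r)
        }
        assert sum(ledger.counts().values()) == len(study_patients)

    def test_statuses_match_generator_truth_exactly(self, config):
        # jitter-free so episode timing noise cannot blur the labels
        import dataclasses

        from bph_persistence.synthetic_data import default_profiles

        profiles = [
            dataclasses.replace(p, refill_jitter_sd=0.0) for p in default_profiles()
        ]
        params = SimulationParams(n_patients=400, seed=21)
        records, deaths, truth = generate_dataset(params, profiles, config)
        _, ledger = select_cohort(records, deaths, config)
        expected = truth.groupby("patient_id")["status"].first().to_dict()
        assert ledger.status_by_patient == expected


class TestSummaries:
    def test_reference_exposure_percentages(self, config):
        # counts with known printed percentages: 3273/4309 men exposed to an
        # AB is 76.0%, 140/4309 deaths is 3.2%
        assert percent(3273, 4309) == 76.0
        assert percent(140, 4309) == 3.2
        assert percent(1533, 4309) == 35.6

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(0.05, 1) == 0.1
        assert round_half_away(2.25, 1) == 2.3
        assert round_half_away(-0.05, 1) == -0.1

    def test_percentages_sum_to_one_hundred(self, config, small_dataset):
        _, (records, deaths, _) = small_dataset
        cohort, _ = select_cohort(records, deaths, config)
        tab = summarize_cohort(cohort)["age_groups"]
        body = tab[tab["age_group"] != "all"]
        assert abs(body["pct"].sum() - 100.0) < 0.5  # rounding slack
        assert body["n"].sum() == len(cohort)

    def test_single_member_cohort_degenerate_iqr(self, config):
        records = _chronic_fills("P1", birth=date(1950, 4, 1), n=3)
        cohort, _ = select_cohort(records, [], config)
        tab = summarize_cohort(cohort)["age_summary"]
        row = tab[tab["group"] == "overall"].iloc[0]
        assert row["median_age"] == 68.0
        assert row["iqr_low"] == row["iqr_high"] == 68.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])


def _exact_permutation_p(a, b, n_mc=40_000, seed=0):
    """Permutation oracle for the two-sided rank-sum p-value (Monte Carlo)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = rankdata(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_mc):
        perm = rng.permutation(len(pooled))
        w = ranks[perm[:n1]].sum()
        count += abs(w - mu) >= abs(w_obs - mu) - 1e-9
    return count / n_mc


class TestWilcoxonRankSum:
    def test_identical_samples_give_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res["z"] == 0.0
        assert res["p_two_sided"] == 1.0

    def test_complete_separation_gives_minimum_rank_sum(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res["statistic"] == 3.0

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(314)
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(0.45, 1.0, 30)
        p_normal = wilcoxon_rank_sum(a, b)["p_two_sided"]
        p_perm = _exact_permutation_p(a, b)
        assert abs(p_normal - p_perm) < 0.01

    def test_ties_handled_with_midranks(self):
        res = wilcoxon_rank_sum([1, 1, 2, 2], [1, 2, 3, 3])
        assert 0.0 < res["p_two_sided"] <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @settings(max_examples=30, derandomize=True)
    @given(
        a=st.lists(st.integers(-50, 50), min_size=3, max_size=15),
        b=st.lists(st.integers(-50, 50), min_size=3, max_size=15),
    )
    def test_invariant_under_monotone_transform(self, a, b):
        base = wilcoxon_rank_sum(a, b)
        f = lambda xs: [math.exp(x / 25.0) for x in xs]
        trans = wilcoxon_rank_sum(f(a), f(b))
        assert base["statistic"] == pytest.approx(trans["statistic"])
        assert base["p_two_sided"] == pytest.approx(trans["p_two_sided"])
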