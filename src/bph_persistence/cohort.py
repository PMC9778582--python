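"""Cohort selection, exclusion ledger, and descriptive summaries.

Implements the new-user eligibility procedure: men aged >= ``min_age_years``
at the reference date, with an index fill inside the index period, no
study-drug fill in the wash-out window, at least one year of database
history before the index date, and at least ``min_prescriptions`` distinct
study-drug dispensation dates during follow-up (chronic use).  Deaths during
follow-up are retained, because death counts as a cause of non-persistence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .records_io import AB, FIVE_ARI, DeathRecord, DispensingRecord, StudyConfig

STATUS_ELIGIBLE = "eligible"
STATUS_NOT_MALE = "not_male"
STATUS_UNDER_AGE = "under_age"
STATUS_WASHOUT = "washout_user"
STATUS_SHORT_HISTORY = "short_history"
STATUS_NO_INDEX_FILL = "no_index_fill"
STATUS_OCCASIONAL = "occasional"

#: Fixed application order; a patient receives the first status that applies.
STATUS_ORDER = (
    STATUS_NOT_MALE,
    STATUS_UNDER_AGE,
    STATUS_WASHOUT,
    STATUS_SHORT_HISTORY,
    STATUS_NO_INDEX_FILL,
    STATUS_OCCASIONAL,
    STATUS_ELIGIBLE,
)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent(n: float, d: float, ndigits: int = 1) -> float:
    if d == 0:
        return float("nan")
    return round_half_away(100.0 * n / d, ndigits)


def completed_years(birth_date: date, reference_date: date) -> int:
    """Age in completed years at the reference date."""
    years = reference_date.year - birth_date.year
    if (reference_date.month, reference_date.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def assign_age_group(
    birth_date: date, reference_date: date, edges: Sequence[int]
) -> str:
    """Bin completed-years age into [e_i, e_{i+1}) groups labelled "e_i-(e_{i+1}-1)"."""
    age = completed_years(birth_date, reference_date)
    if age < edges[0]:
        raise ValueError(f"age {age} below first edge {edges[0]}")
    if age >= edges[-1]:
        warnings.warn(f"age {age} beyond last age-group edge {edges[-1]}")
        return "out_of_range"
    for lo, hi in zip(edges, edges[1:]):
        if lo <= age < hi:
            return f"{lo}-{hi - 1}"
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class CohortMember:
    """An eligible subject with index date and exposure summary."""

    patient_id: str
    age_at_reference: int
    age_group: str
    young_old: str  # "young" (< cut) or "old" (>= cut)
    index_date: date
    followup_end: date
    death_date: date | None
    drugs_prescribed: frozenset[str]
    classes_prescribed: frozenset[str]
    n_fill_dates: int

    @property
    def died_in_followup(self) -> bool:
        return (
            self.death_date is not None
            and self.index_date <= self.death_date < self.followup_end
        )


@dataclass
class ExclusionLedger:
    """Final, mutually exclusive status of every patient with >= 1 study-drug record."""

    status_by_patient: dict[str, str] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in STATUS_ORDER}
        for s in self.status_by_patient.values():
            out[s] += 1
        return out

    @property
    def n_patients(self) -> int:
        return len(self.status_by_patient)

    def to_frame(self) -> pd.DataFrame:
        counts = self.counts()
        return pd.DataFrame(
            {"status": list(counts), "n": list(counts.values())}
        )


def select_cohort(
    records: Iterable[DispensingRecord],
    deaths: Iterable[DeathRecord] | None,
    config: StudyConfig,
) -> tuple[list[CohortMember], ExclusionLedger]:
    """Apply the eligibility procedure and return (cohort, exclusion ledger).

    Exclusions are applied in the fixed order not_male -> under_age ->
    washout_user -> short_history -> no_index_fill -> occasional so that
    ledger counts are reproducible.  An empty record set yields an empty
    cohort with a zeroed ledger.
    """
    death_by: dict[str, date] = {}
    for d in deaths or ():
        death_by[d.patient_id] = d.death_date

    by_patient: dict[str, list[DispensingRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)

    ws, we = config.washout_window
    istart, iend = config.index_period
    ledger = ExclusionLedger()
    cohort: list[CohortMember] = []

    for pid in sorted(by_patient):
        recs = by_patient[pid]
        study = sorted(
            (r for r in recs if config.is_study_drug(r)),
            key=lambda r: r.dispensation_date,
        )
        if not study:
            continue  # ledger covers patients with >= 1 study-drug record

        if any(r.sex != "M" for r in recs):
            ledger.status_by_patient[pid] = STATUS_NOT_MALE
            continue

        birth = recs[0].birth_date
        age = completed_years(birth, config.reference_date)
        if age < config.min_age_years:
            ledger.status_by_patient[pid] = STATUS_UNDER_AGE
            continue

        if any(ws <= r.dispensation_date < we for r in study):
            ledger.status_by_patient[pid] = STATUS_WASHOUT
            continue

        index_fills = [r for r in study if istart <= r.dispensation_date < iend]
        if index_fills:
            index_date = min(r.dispensation_date for r in index_fills)
            earliest_any = min(r.dispensation_date for r in recs)
            if earliest_any > index_date - timedelta(days=config.min_history_days):
                ledger.status_by_patient[pid] = STATUS_SHORT_HISTORY
                continue
        else:
            ledger.status_by_patient[pid] = STATUS_NO_INDEX_FILL
            continue

        fe = config.followup_end(index_date)
        fu_fills = [r for r in study if index_date <= r.dispensation_date < fe]
        if config.per_drug_prescriptions:
            per_drug: dict[str, set[date]] = {}
            for r in fu_fills:
                per_drug.setdefault(r.drug_name, set()).add(r.dispensation_date)
            n_dates = max((len(v) for v in per_drug.values()), default=0)
        else:
            n_dates = len({r.dispensation_date for r in fu_fills})
        if n_dates < config.min_prescriptions:
            ledger.status_by_patient[pid] = STATUS_OCCASIONAL
            continue

        ledger.status_by_patient[pid] = STATUS_ELIGIBLE
        drugs = frozenset(r.drug_name for r in fu_fills)
        classes = frozenset(
            config.drug_class(r.atc_code) for r in fu_fills
        )
        cohort.append(
            CohortMember(
                patient_id=pid,
                age_at_reference=age,
                age_group=assign_age_group(
                    birth, config.reference_date, config.age_group_edges
                ),
                young_old="young" if age < config.young_old_cut else "old",
                index_date=index_date,
                followup_end=fe,
                death_date=death_by.get(pid),
                drugs_prescribed=drugs,
                classes_prescribed=classes,
                n_fill_dates=len({r.dispensation_date for r in fu_fills}),
            )
        )

    return cohort, ledger


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------


def _age_quartiles(ages: Sequence[int]) -> tuple[float, float, float]:
    a = np.asarray(ages, dtype=float)
    return (
        float(np.median(a)),
        float(np.percentile(a, 25)),
        float(np.percentile(a, 75)),
    )


def summarize_cohort(cohort: Sequence[CohortMember]) -> dict[str, pd.DataFrame]:
    """Descriptive tables of the cohort.

    Returns a dict of data frames:

    ``age_groups``
        N and percentage per age group (one decimal, half away from zero).
    ``exposure``
        counts/percentages exposed to >= 1 AB, >= 1 5ARI, both classes, and
        deaths during follow-up; denominators are the cohort size.
    ``age_summary``
        median age and IQR overall, per class, and per drug.
    """
    if not cohort:
        raise ValueError("empty cohort")
    n = len(cohort)

    groups = sorted({m.age_group for m in cohort}, key=lambda s: (s == "out_of_range", s))
    rows = []
    for g in groups:
        cnt = sum(1 for m in cohort if m.age_group == g)
        rows.append({"age_group": g, "n": cnt, "pct": percent(cnt, n)})
    rows.append({"age_group": "all", "n": n, "pct": percent(n, n)})
    age_groups = pd.DataFrame(rows)

    n_ab = sum(1 for m in cohort if AB in m.classes_prescribed)
    n_5ari = sum(1 for m in cohort if FIVE_ARI in m.classes_prescribed)
    n_both = sum(1 for m in cohort if len(m.classes_prescribed) >= 2)
    n_dead = sum(1 for m in cohort if m.died_in_followup)
    exposure = pd.DataFrame(
        [
            {"group": "at_least_one_AB", "n": n_ab, "pct": percent(n_ab, n)},
            {"group": "at_least_one_5ARI", "n": n_5ari, "pct": percent(n_5ari, n)},
            {"group": "both_classes", "n": n_both, "pct": percent(n_both, n)},
            {"group": "single_class", "n": n - n_both, "pct": percent(n - n_both, n)},
            {"group": "died_in_followup", "n": n_dead, "pct": percent(n_dead, n)},
        ]
    )

    def _row(label: str, members: list[CohortMember]) -> dict:
        med, q1, q3 = _age_quartiles([m.age_at_reference for m in members])
        return {
            "group": label,
            "n": len(members),
            "median_age": med,
            "iqr_low": q1,
            "iqr_high": q3,
        }

    summary_rows = [_row("overall", list(cohort))]
    for cls in (AB, FIVE_ARI):
        members = [m for m in cohort if cls in m.classes_prescribed]
        if members:
            summary_rows.append(_row(cls, members))
    drugs = sorted({d for m in cohort for d in m.drugs_prescribed})
    for drug in drugs:
        members = [m for m in cohort if drug in m.drugs_prescribed]
        summary_rows.append(_row(drug, members))
    age_summary = pd.DataFrame(summary_rows)

    return {"age_groups": age_groups, "exposure": exposure, "age_summary": age_summary}


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test (normal approximation with midranks, tie-corrected
# variance, and continuity correction) — used for the age comparison between
# drug classes.  Implemented here so the test statistic and p-value are under
# the package's control; exact-permutation enumeration is its oracle in tests.
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(sample_a, sample_b) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns the rank sum of ``sample_a`` (with midranks for ties), the
    continuity-corrected normal z statistic with tie-corrected variance, and
    the two-sided p-value.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = rankdata(np.concatenate([a, b]))
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    diff = w - mu
    if var <= 0 or diff == 0:
        z = 0.0
    else:
        z = (diff - 0.5 * math.copysign(1.0, diff)) / math.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return {"statistic": w, "z": z, "p_two_sided": p}
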