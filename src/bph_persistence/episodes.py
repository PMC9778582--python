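"""Treatment-episode construction under the grace-period rule.

A patient's dispensation stream (per drug, or per pharmacological class) is
scanned in date order.  Each dispensation supplies ``n_packages x
ddd_per_package`` days of drug.  A new dispensation continues the current
episode iff it falls within the grace period — ``grace_multiplier`` (default
1.5) times the previous dispensation's own supply duration — measured from
the previous dispensation date (default) or from the previous supply end
(``gap_anchor="supply_end"``).  Early refills carry over: supply that would
overlap is shifted forward (stockpiling), uncapped by default.

Discontinuation is placed at the supply end of the episode's last span; an
episode whose supply end plus its final grace period extends past the end of
follow-up cannot be observed to discontinue and is censored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Sequence

from .cohort import CohortMember
from .records_io import DispensingRecord, StudyConfig

LEVEL_DRUG = "drug"
LEVEL_CLASS = "class"

TERM_GAP = "gap"
TERM_DEATH = "death"
TERM_FOLLOWUP_END = "followup_end"
TERM_CENSORED = "censored_alive"


def supply_duration(record: DispensingRecord) -> float:
    """Days of supply of one dispensation: n_packages x DDDs per package."""
    days = record.n_packages * record.ddd_per_package
    if not days > 0:
        raise ValueError("non-positive supply duration")
    return days


def grace_period(duration_days: float, multiplier: float) -> float:
    """Grace period of a dispensation: multiplier x its own supply duration."""
    if not duration_days > 0:
        raise ValueError("duration must be positive")
    if not multiplier > 0:
        raise ValueError("grace multiplier must be positive")
    return multiplier * duration_days


@dataclass(frozen=True)
class SupplySpan:
    """One dispensation (same-day fills of one key merged) as a supply interval."""

    key: str  # drug name, or class label
    drug_name: str
    start: date
    duration_days: float

    @property
    def end(self) -> date:
        return self.start + timedelta(days=math.ceil(self.duration_days))


@dataclass
class TreatmentEpisode:
    """A maximal run of continuous drug supply under the grace-period rule."""

    patient_id: str
    level: str
    key: str
    episode_start: date
    supply_end: date
    n_dispensations: int
    terminated_by: str
    last_duration_days: float  # supply duration of the final span (grace basis)
    last_fill: date


@dataclass(frozen=True)
class SurvivalObservation:
    """Time to first discontinuation (event=1) or censoring (event=0)."""

    patient_id: str
    key: str
    level: str
    time_days: int
    event: int
    age_group: str = ""
    young_old: str = ""


def spans_from_records(
    fills: Iterable[DispensingRecord], config: StudyConfig, level: str
) -> list[SupplySpan]:
    """Build date-sorted supply spans for one patient, merging same-day fills
    of the same key (durations summed)."""
    merged: dict[tuple[str, date], dict] = {}
    for r in fills:
        if level == LEVEL_DRUG:
            key = r.drug_name
        elif level == LEVEL_CLASS:
            cls = config.drug_class(r.atc_code)
            if cls is None:
                continue
            key = cls
        else:
            raise ValueError(f"unknown level: {level}")
        slot = merged.setdefault(
            (key, r.dispensation_date),
            {"drug": r.drug_name, "days": 0.0},
        )
        slot["days"] += supply_duration(r)
    return [
        SupplySpan(key=key, drug_name=v["drug"], start=d, duration_days=v["days"])
        for (key, d), v in sorted(merged.items(), key=lambda kv: (kv[0][1], kv[0][0]))
    ]


def _gap_continues(
    fill: date, prev_fill: date, prev_supply_end: date, prev_duration: float, config: StudyConfig
) -> bool:
    grace = grace_period(prev_duration, config.grace_multiplier)
    if config.gap_anchor == "fill":
        return (fill - prev_fill).days <= grace
    # supply-end anchor: allowed gap beyond supply exhaustion is the grace
    # period less the supply itself, i.e. (multiplier - 1) x duration.
    return (fill - prev_supply_end).days <= grace - prev_duration


def build_episodes(
    patient_spans: Sequence[SupplySpan],
    level: str,
    config: StudyConfig,
    *,
    patient_id: str = "",
    death_date: date | None = None,
    followup_end: date | None = None,
) -> list[TreatmentEpisode]:
    """Scan a patient's spans in date order and emit treatment episodes.

    ``patient_spans`` must be sorted by start date (unsorted input is an
    error, never silently sorted).  Non-final episodes terminate by ``gap``;
    the final episode of each key is classified against the optional death
    date and follow-up end.
    """
    for a, b in zip(patient_spans, patient_spans[1:]):
        if b.start < a.start:
            raise ValueError("spans must be sorted by start date")

    by_key: dict[str, list[SupplySpan]] = {}
    for s in patient_spans:
        by_key.setdefault(s.key, []).append(s)

    episodes: list[TreatmentEpisode] = []
    for key in sorted(by_key):
        spans = by_key[key]
        cur: TreatmentEpisode | None = None
        for s in spans:
            if cur is None:
                cur = _open_episode(patient_id, level, key, s)
                continue
            if _gap_continues(s.start, cur.last_fill, cur.supply_end, cur.last_duration_days, config):
                effective_start = max(s.start, cur.supply_end)
                if config.stockpile_cap_days is not None:
                    cap_end = s.start + timedelta(days=config.stockpile_cap_days)
                    effective_start = min(effective_start, cap_end)
                cur.supply_end = effective_start + timedelta(days=math.ceil(s.duration_days))
                cur.n_dispensations += 1
                cur.last_duration_days = s.duration_days
                cur.last_fill = s.start
            else:
                cur.terminated_by = TERM_GAP
                episodes.append(cur)
                cur = _open_episode(patient_id, level, key, s)
        if cur is not None:
            cur.terminated_by = _classify_final(cur, death_date, followup_end, config)
            episodes.append(cur)
    return episodes


def _open_episode(patient_id: str, level: str, key: str, s: SupplySpan) -> TreatmentEpisode:
    return TreatmentEpisode(
        patient_id=patient_id,
        level=level,
        key=key,
        episode_start=s.start,
        supply_end=s.end,
        n_dispensations=1,
        terminated_by=TERM_GAP,
        last_duration_days=s.duration_days,
        last_fill=s.start,
    )


def _classify_final(
    ep: TreatmentEpisode,
    death_date: date | None,
    followup_end: date | None,
    config: StudyConfig,
) -> str:
    if (
        death_date is not None
        and ep.episode_start <= death_date <= ep.supply_end
        and (followup_end is None or death_date < followup_end)
    ):
        return TERM_DEATH
    if followup_end is not None:
        if ep.supply_end >= followup_end:
            return TERM_FOLLOWUP_END
        grace = grace_period(ep.last_duration_days, config.grace_multiplier)
        if ep.supply_end + timedelta(days=grace) > followup_end:
            return TERM_CENSORED
    return TERM_GAP


def time_to_discontinuation(
    episodes: Sequence[TreatmentEpisode],
    member: CohortMember,
    config: StudyConfig,
) -> SurvivalObservation:
    """Survival observation from a patient's first episode of one key.

    Event=1 at the episode's supply end when it closed with a refill gap
    before the follow-up end, or at the death date when death fell inside
    the episode; otherwise censored.  Times are measured from the episode
    start (the key's first fill) and capped at ``followup_days``; event
    times beyond the follow-up horizon are censored at the horizon.
    """
    if not episodes:
        raise ValueError("no episodes")
    first = episodes[0]
    fe = member.followup_end
    horizon = min(config.followup_days, (fe - first.episode_start).days)

    if first.terminated_by == TERM_DEATH:
        t = (member.death_date - first.episode_start).days
        event = 1
    elif first.terminated_by == TERM_GAP:
        t = (first.supply_end - first.episode_start).days
        event = 1
    else:  # censored_alive / followup_end
        t = horizon
        event = 0
    if t > horizon:
        t, event = horizon, 0
    t = max(t, 0)
    return SurvivalObservation(
        patient_id=first.patient_id or member.patient_id,
        key=first.key,
        level=first.level,
        time_days=int(t),
        event=event,
        age_group=member.age_group,
        young_old=member.young_old,
    )
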