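"""Synthetic dispensing-record generator with known ground truth.

The generator emulates an administrative pharmacy-claims database for the
seven BPH/BPO study drugs.  Discontinuation behaviour is simulated at the
episode level: each chronic user carries a latent intended treatment span
drawn from the drug's time-to-discontinuation distribution, and refills are
noisy observations of that span (one package per fill, spaced one supply
duration apart plus zero-mean jitter, clipped so the grace rule can always
reconstruct the episode).  Within-class switching draws a new drug and a
fresh latent span.  Death truncates all refill sequences.

Chronic users always receive at least two dispensations of their initial
drug: single-fill behaviour is modelled by the separate "occasional"
contaminant subpopulation rather than by short latent spans, so the
chronic-use cohort filter never silently reclassifies intended-chronic
patients.  Further contaminants exercise the remaining exclusions:
under-age men, wash-out-period users, and short-history patients.

The returned truth table carries, per patient and drug, the latent
discontinuation day, the event time and indicator the episode rules should
recover, and the patient's eligibility status — so every downstream stage
is testable without external data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records_io import (
    AB,
    FIVE_ARI,
    STUDY_DRUG_ATC,
    DeathRecord,
    DispensingRecord,
    StudyConfig,
    write_deaths,
    write_records,
)

LN2 = math.log(2.0)

#: Non-study drug used to give patients database history.
HISTORY_DRUG = ("ramipril", "C09AA05", 28.0)

TRUTH_COLUMNS = [
    "patient_id",
    "status",
    "drug_name",
    "start_day",
    "true_discontinuation_day",
    "expected_time_days",
    "expected_event",
]


@dataclass(frozen=True)
class DrugProfile:
    """Behavioural parameters of one study drug.

    ``ddd_per_package`` doubles as the days of supply per package;
    ``median_days`` parameterises the time-to-discontinuation distribution
    (for the Weibull it is the distribution median, converted to the scale
    internally); ``market_share`` is the within-class share of new users.
    """

    drug_name: str
    atc_code: str
    ddd_per_package: float = 30.0
    discontinuation_dist: str = "exponential"  # or "weibull"
    median_days: float = 100.0
    shape: float = 1.5  # Weibull only
    refill_jitter_sd: float = 0.0
    market_share: float = 1.0

    def __post_init__(self):
        if not self.median_days > 0:
            raise ValueError("median must be positive")
        if self.refill_jitter_sd < 0:
            raise ValueError("jitter SD must be non-negative")
        if self.discontinuation_dist not in ("exponential", "weibull"):
            raise ValueError("distribution must be exponential or weibull")


def default_profiles() -> list[DrugProfile]:
    """The seven study drugs with medians and within-class market shares
    anchored to the persistence and exposure pattern the study reports."""
    ab = [
        ("alfuzosin", 278.0, 584),
        ("tamsulosin", 101.0, 2057),
        ("terazosin", 28.0, 219),
        ("silodosin", 120.0, 1074),
        ("doxazosin", 81.0, 88),
    ]
    fari = [
        ("dutasteride", 272.0, 1064),
        ("finasteride", 97.0, 416),
    ]
    out = []
    for group in (ab, fari):
        total = sum(w for _, _, w in group)
        for name, median, w in group:
            out.append(
                DrugProfile(
                    drug_name=name,
                    atc_code=STUDY_DRUG_ATC[name],
                    ddd_per_package=30.0,
                    discontinuation_dist="exponential",
                    median_days=median,
                    refill_jitter_sd=3.0,
                    market_share=w / total,
                )
            )
    return out


#: Age-group mix of the study population (shares of the cohort).
DEFAULT_AGE_DIST: Mapping[str, float] = {
    "40-49": 0.023,
    "50-59": 0.122,
    "60-69": 0.285,
    "70-79": 0.356,
    "80-89": 0.194,
    "90-100": 0.019,
}


@dataclass(frozen=True)
class SimulationParams:
    """Population-level parameters of one simulated dataset."""

    n_patients: int = 5000
    seed: int = 0
    age_dist: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_DIST))
    class_mix: tuple[float, float, float] = (0.666, 0.222, 0.112)  # AB, 5ARI, both
    switch_prob: float = 0.25
    death_rate_annual: float = 0.032
    frac_occasional: float = 0.12
    frac_underage: float = 0.05
    frac_washout_users: float = 0.08
    frac_short_history: float = 0.05

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        fracs = (
            self.frac_occasional,
            self.frac_underage,
            self.frac_washout_users,
            self.frac_short_history,
        )
        probs = fracs + (self.switch_prob, self.death_rate_annual) + tuple(self.class_mix)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if sum(fracs) > 1:
            raise ValueError("infeasible mix: contaminant fractions sum above 1")


def expected_eligible_fraction(params: SimulationParams) -> float:
    """Closed-form expected fraction of truth-eligible patients.

    Contaminant categories are drawn from one categorical per patient, so
    the eligible fraction is one minus the contaminant fractions.  (Death
    before the second fill can demote an intended-chronic patient to
    "occasional"; at the default death rate this shifts the fraction by
    under 0.3 percentage points and is ignored here.)
    """
    return 1.0 - (
        params.frac_occasional
        + params.frac_underage
        + params.frac_washout_users
        + params.frac_short_history
    )


def sample_discontinuation(profile: DrugProfile, rng: np.random.Generator) -> float:
    """Draw one latent time-to-discontinuation (days) from the profile."""
    if profile.discontinuation_dist == "exponential":
        t = rng.exponential(scale=profile.median_days / LN2)
    else:
        scale = profile.median_days / LN2 ** (1.0 / profile.shape)
        t = scale * rng.weibull(profile.shape)
    return max(t, 0.5)


def sample_refill_sequence(
    profile: DrugProfile,
    true_discontinuation_day: float,
    rng: np.random.Generator,
    grace_multiplier: float = 1.5,
    min_fills: int = 1,
) -> list[int]:
    """Dispensation day offsets (first fill at day 0) for one latent span.

    Successive fills are spaced one supply duration apart plus zero-mean
    Gaussian jitter, clipped into [1, grace_multiplier x supply] so episode
    reconstruction under the grace rule always recovers a single episode
    whose supply end lies within one package duration of the latent
    discontinuation day.  A jitter SD large enough that unclipped spacing
    would exceed the grace bound with probability above 10% triggers a
    warning (ground truth would no longer be recoverable).
    """
    if not true_discontinuation_day > 0:
        raise ValueError("true discontinuation day must be positive")
    s = profile.ddd_per_package
    sd = profile.refill_jitter_sd
    bound = grace_multiplier * s
    if sd > 0:
        from scipy.stats import norm

        if norm.sf((grace_multiplier - 1.0) * s / sd) > 0.10:
            warnings.warn(
                "refill jitter SD so large that spacing exceeds the grace "
                "bound with probability > 10%; ground truth may not be "
                "recoverable"
            )
    days = [0]
    while len(days) < 1000:
        gap = s + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        gap_i = int(round(min(max(gap, 1.0), bound)))
        gap_i = max(1, min(gap_i, int(math.floor(bound))))
        nxt = days[-1] + gap_i
        if nxt >= true_discontinuation_day and len(days) >= min_fills:
            break
        days.append(nxt)
    return days


def _supply_end_day(days: Sequence[int], supply: float) -> int:
    """Supply-end day of one episode under the carry-over (stockpiling) rule."""
    end = days[0] + math.ceil(supply)
    for d in days[1:]:
        end = max(d, end) + math.ceil(supply)
    return end


def _expected_observation(
    fill_days: Sequence[int],
    supply: float,
    death_day: int | None,
    followup_days: int,
    grace_multiplier: float,
) -> tuple[int, int]:
    """Event time/indicator the episode rules should recover for one drug."""
    start = fill_days[0]
    horizon = followup_days - start
    sup_end = _supply_end_day(fill_days, supply)
    if (
        death_day is not None
        and start <= death_day <= sup_end
        and death_day < followup_days
    ):
        t, event = death_day - start, 1
    elif sup_end >= followup_days:
        t, event = horizon, 0
    elif sup_end + grace_multiplier * supply > followup_days:
        t, event = horizon, 0
    else:
        t, event = sup_end - start, 1
    if t > horizon:
        t, event = horizon, 0
    return max(t, 0), event


def _draw_age(params, config, rng, underage: bool) -> int:
    if underage:
        return int(rng.integers(18, config.min_age_years))
    labels = list(params.age_dist)
    probs = np.array([params.age_dist[g] for g in labels], dtype=float)
    probs = probs / probs.sum()
    g = labels[rng.choice(len(labels), p=probs)]
    lo, hi = g.split("-")
    return int(rng.integers(int(lo), int(hi) + 1))


def _birth_date(age: int, reference: date, rng) -> date:
    try:
        anniversary = reference.replace(year=reference.year - age)
    except ValueError:  # Feb 29 reference
        anniversary = reference.replace(year=reference.year - age, day=reference.day - 1)
    return anniversary - timedelta(days=int(rng.integers(0, 365)))


def _pick_drug(
    profiles: Sequence[DrugProfile], cls: str, config: StudyConfig,
    rng: np.random.Generator, exclude: set[str],
) -> DrugProfile | None:
    pool = [
        p
        for p in profiles
        if config.drug_class(p.atc_code) == cls and p.drug_name not in exclude
    ]
    if not pool:
        return None
    w = np.array([p.market_share for p in pool], dtype=float)
    return pool[rng.choice(len(pool), p=w / w.sum())]


def generate_dataset(
    params: SimulationParams,
    profiles: Sequence[DrugProfile] | None = None,
    config: StudyConfig | None = None,
) -> tuple[list[DispensingRecord], list[DeathRecord], pd.DataFrame]:
    """Generate (records, deaths, truth) for one simulated population.

    Deterministic given (params, profiles, config): the same inputs always
    produce byte-identical outputs when written through the record writers.
    """
    profiles = list(profiles) if profiles is not None else default_profiles()
    config = config or StudyConfig()
    rng = np.random.default_rng(params.seed)

    istart, iend = config.index_period
    ws, we = config.washout_window
    fu = config.followup_days
    cat_names = ("eligible", "occasional", "under_age", "washout_user", "short_history")
    cat_probs = np.array(
        [
            expected_eligible_fraction(params),
            params.frac_occasional,
            params.frac_underage,
            params.frac_washout_users,
            params.frac_short_history,
        ]
    )

    records: list[DispensingRecord] = []
    deaths: list[DeathRecord] = []
    truth_rows: list[dict] = []

    for i in range(params.n_patients):
        pid = f"P{i:06d}"
        cat = cat_names[rng.choice(len(cat_names), p=cat_probs)]
        age = _draw_age(params, config, rng, underage=(cat == "under_age"))
        birth = _birth_date(age, config.reference_date, rng)
        index_date = istart + timedelta(days=int(rng.integers(0, (iend - istart).days)))

        death_day: int | None = None
        if rng.random() < params.death_rate_annual:
            death_day = int(rng.integers(1, fu + 1))
            deaths.append(DeathRecord(pid, index_date + timedelta(days=death_day)))

        def emit(drug: str, atc: str, ddd: float, on: date):
            records.append(
                DispensingRecord(
                    patient_id=pid,
                    birth_date=birth,
                    sex="M",
                    dispensation_date=on,
                    atc_code=atc,
                    drug_name=drug,
                    n_packages=1,
                    ddd_per_package=ddd,
                )
            )

        # Database history for everyone except short-history patients.
        if cat != "short_history":
            hist_day = int(rng.integers(400, 1100))
            emit(*HISTORY_DRUG, index_date - timedelta(days=hist_day))
        else:
            emit(*HISTORY_DRUG, index_date - timedelta(days=int(rng.integers(30, 300))))

        # Class assignment, restricted to classes the profile list covers.
        available = {config.drug_class(p.atc_code) for p in profiles}
        mix = np.array(params.class_mix, dtype=float)
        if AB not in available:
            mix[0] = mix[2] = 0.0
        if FIVE_ARI not in available:
            mix[1] = mix[2] = 0.0
        if mix.sum() <= 0:
            raise ValueError("profiles cover no class compatible with class_mix")
        mix = mix / mix.sum()
        arm = ("AB", "5ARI", "both")[rng.choice(3, p=mix)]
        classes = [AB, FIVE_ARI] if arm == "both" else [AB if arm == "AB" else FIVE_ARI]

        if cat == "occasional":
            prof = _pick_drug(profiles, classes[0], config, rng, exclude=set())
            if death_day is None or death_day > 0:
                emit(prof.drug_name, prof.atc_code, prof.ddd_per_package, index_date)
            truth_rows.append(
                {
                    "patient_id": pid,
                    "status": cat,
                    "drug_name": prof.drug_name,
                    "start_day": 0,
                    "true_discontinuation_day": float("nan"),
                    "expected_time_days": float("nan"),
                    "expected_event": float("nan"),
                }
            )
            continue

        if cat == "washout_user":
            wo_prof = _pick_drug(profiles, classes[0], config, rng, exclude=set())
            wo_day = int(rng.integers(0, (we - ws).days))
            emit(
                wo_prof.drug_name,
                wo_prof.atc_code,
                wo_prof.ddd_per_package,
                ws + timedelta(days=wo_day),
            )

        # Chronic refill chains (all remaining categories behave chronically).
        used: set[str] = set()
        n_fill_dates: set[int] = set()
        drug_rows: list[dict] = []
        for cls in classes:
            start_day = 0
            first_in_chain = True
            while start_day < fu:
                prof = _pick_drug(profiles, cls, config, rng, exclude=used)
                if prof is None:
                    break
                used.add(prof.drug_name)
                latent = sample_discontinuation(prof, rng)
                horizon = fu + 30 - start_day
                capped = min(latent, horizon)
                offs = sample_refill_sequence(
                    prof,
                    capped,
                    rng,
                    grace_multiplier=config.grace_multiplier,
                    min_fills=2 if first_in_chain else 1,
                )
                fill_days = [start_day + o for o in offs]
                if death_day is not None:
                    fill_days = [d for d in fill_days if d < death_day]
                if fill_days:
                    for d in fill_days:
                        emit(
                            prof.drug_name,
                            prof.atc_code,
                            prof.ddd_per_package,
                            index_date + timedelta(days=d),
                        )
                        if 0 <= d < fu:
                            n_fill_dates.add(d)
                    t_exp, e_exp = _expected_observation(
                        fill_days,
                        prof.ddd_per_package,
                        death_day,
                        fu,
                        config.grace_multiplier,
                    )
                    drug_rows.append(
                        {
                            "patient_id": pid,
                            "status": cat,
                            "drug_name": prof.drug_name,
                            "start_day": fill_days[0],
                            "true_discontinuation_day": round(start_day + latent, 3),
                            "expected_time_days": t_exp,
                            "expected_event": e_exp,
                        }
                    )
                first_in_chain = False
                if latent >= horizon or death_day is not None and not fill_days:
                    break
                end_day = (
                    _supply_end_day(fill_days, prof.ddd_per_package)
                    if fill_days
                    else start_day
                )
                if rng.random() >= params.switch_prob:
                    break
                start_day = end_day + int(
                    rng.uniform(0.0, 2.0 * prof.ddd_per_package)
                )

        # Death can leave an intended-chronic patient with < 2 distinct fill
        # dates; the cohort rules then classify him as occasional, and the
        # truth table must agree.
        status = cat
        if cat == "eligible" and len(n_fill_dates) < config.min_prescriptions:
            status = "occasional"
        if not drug_rows:
            drug_rows.append(
                {
                    "patient_id": pid,
                    "status": status,
                    "drug_name": "",
                    "start_day": float("nan"),
                    "true_discontinuation_day": float("nan"),
                    "expected_time_days": float("nan"),
                    "expected_event": float("nan"),
                }
            )
        for row in drug_rows:
            row["status"] = status
            truth_rows.append(row)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return records, deaths, truth


def write_dataset(records, deaths, truth: pd.DataFrame, out_dir) -> dict[str, Path]:
    """Write records/deaths CSVs in the shared dialect plus the truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out / "records.csv",
        "deaths": out / "deaths.csv",
        "truth": out / "truth.csv",
    }
    write_records(records, paths["records"])
    write_deaths(deaths, paths["deaths"])
    truth.to_csv(paths["truth"], index=False)
    return paths
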