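"""Dispensing-record schema, study configuration, and delimited-text I/O.

The whole analysis consumes one table with a row per pharmacy dispensation
(anonymised patient id, birth date, sex, dispensation date, ATC code, drug
name, number of packages, DDDs per package), an optional death table, and a
:class:`StudyConfig` that carries every tunable of the study design (index
period, wash-out window, grace multiplier, follow-up horizon, age grid).

This module also fixes the shared domain vocabulary: the seven study drugs
for BPH/BPO-associated LUTS and their pharmacological classes — five
alpha-1-adrenoceptor antagonists (ABs) and two 5-alpha-reductase inhibitors
(5ARIs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
import re
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

#: Class labels.
AB = "AB"
FIVE_ARI = "5ARI"

#: WHO ATC codes of the seven study drugs.  Doxazosin sits in the
#: cardiovascular chapter (C02CA) even though it is prescribed for BPH/BPO,
#: hence the C02CA entry in the default class map.
STUDY_DRUG_ATC: Mapping[str, str] = {
    "alfuzosin": "G04CA01",
    "tamsulosin": "G04CA02",
    "terazosin": "G04CA03",
    "silodosin": "G04CA04",
    "doxazosin": "C02CA04",
    "finasteride": "G04CB01",
    "dutasteride": "G04CB02",
}

AB_DRUGS = ("alfuzosin", "doxazosin", "silodosin", "tamsulosin", "terazosin")
FIVE_ARI_DRUGS = ("finasteride", "dutasteride")
STUDY_DRUGS = AB_DRUGS + FIVE_ARI_DRUGS

DEFAULT_CLASS_MAP: Mapping[str, str] = {"G04CA": AB, "G04CB": FIVE_ARI, "C02CA": AB}

# Full 7-character ATC, and the legal prefixes of one (codes may be partial).
_ATC_FULL = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")
_ATC_PARTIAL = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")

RECORD_COLUMNS = [
    "patient_id",
    "birth_date",
    "sex",
    "dispensation_date",
    "atc_code",
    "drug_name",
    "n_packages",
    "ddd_per_package",
]

DEATH_COLUMNS = ["patient_id", "death_date"]


@dataclass(frozen=True)
class DispensingRecord:
    """One pharmacy dispensation event.

    ``ddd_per_package`` is the number of Defined Daily Doses contained in one
    package; under the once-daily regimens studied here it equals the days of
    supply one package provides.
    """

    patient_id: str
    birth_date: date
    sex: str
    dispensation_date: date
    atc_code: str
    drug_name: str
    n_packages: int
    ddd_per_package: float

    def validate(self) -> None:
        """Raise ``ValueError`` with a short reason on any invariant breach."""
        if not self.patient_id:
            raise ValueError("empty patient id")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be M or F")
        if self.n_packages < 1:
            raise ValueError("non-positive package count")
        if not self.ddd_per_package > 0:
            raise ValueError("non-positive DDD per package")
        if self.dispensation_date < self.birth_date:
            raise ValueError("dispensation before birth")
        if not (_ATC_FULL.match(self.atc_code) or _ATC_PARTIAL.match(self.atc_code)):
            raise ValueError("malformed ATC code")


@dataclass(frozen=True)
class DeathRecord:
    """Date of death for one patient (optional side table)."""

    patient_id: str
    death_date: date


def _as_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))


def _interval(value) -> tuple[date, date]:
    start, end = value
    return (_as_date(start), _as_date(end))


@dataclass(frozen=True)
class StudyConfig:
    """Every design constant of the persistence study.

    Defaults reproduce the study design: men aged >= 40 years at the
    reference date 2018-04-01, a wash-out window covering the first quarter
    of 2018 (any study-drug fill there marks a prevalent user), at least one
    year of database history before the index date, 365 days of follow-up,
    at least 2 study-drug prescriptions (chronic use), and a grace period of
    1.5 times each dispensation's supply duration.
    """

    reference_date: date = date(2018, 4, 1)
    min_age_years: int = 40
    index_period: tuple[date, date] = (date(2018, 4, 1), date(2018, 7, 1))
    washout_window: tuple[date, date] = (date(2018, 1, 1), date(2018, 4, 1))
    min_history_days: int = 365
    followup_days: int = 365
    min_prescriptions: int = 2
    per_drug_prescriptions: bool = False
    grace_multiplier: float = 1.5
    gap_anchor: str = "fill"  # or "supply_end"
    stockpile_cap_days: int | None = None
    class_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MAP)
    )
    age_group_edges: tuple[int, ...] = (40, 50, 60, 70, 80, 90, 101)
    young_old_cut: int = 70
    ci_method: str = "loglog"  # or "linear"

    def __post_init__(self):
        object.__setattr__(self, "reference_date", _as_date(self.reference_date))
        object.__setattr__(self, "index_period", _interval(self.index_period))
        object.__setattr__(self, "washout_window", _interval(self.washout_window))
        object.__setattr__(self, "age_group_edges", tuple(int(e) for e in self.age_group_edges))
        object.__setattr__(self, "class_map", dict(self.class_map))
        if self.min_age_years < 0:
            raise ValueError("min_age_years must be non-negative")
        if not self.grace_multiplier > 0:
            raise ValueError("grace_multiplier must be positive")
        if self.followup_days <= 0:
            raise ValueError("followup_days must be positive")
        if self.min_history_days < 0:
            raise ValueError("min_history_days must be non-negative")
        if self.min_prescriptions < 1:
            raise ValueError("min_prescriptions must be >= 1")
        if self.gap_anchor not in ("fill", "supply_end"):
            raise ValueError("gap_anchor must be 'fill' or 'supply_end'")
        if self.ci_method not in ("loglog", "linear"):
            raise ValueError("ci_method must be 'loglog' or 'linear'")
        if any(b <= a for a, b in zip(self.age_group_edges, self.age_group_edges[1:])):
            raise ValueError("age_group_edges must be strictly increasing")
        if len(self.age_group_edges) < 2:
            raise ValueError("age_group_edges needs at least two edges")
        for iv, name in ((self.index_period, "index_period"), (self.washout_window, "washout_window")):
            if iv[1] <= iv[0]:
                raise ValueError(f"{name} must be a non-empty [start, end) interval")
        if self.index_period[0] != self.washout_window[1]:
            raise ValueError("index_period must start where washout_window ends")

    # -- derived vocabulary -------------------------------------------------

    def drug_class(self, atc_code: str) -> str | None:
        """Class label for an ATC code, or None for a non-study drug."""
        for prefix, label in self.class_map.items():
            if atc_code.startswith(prefix):
                return label
        return None

    def is_study_drug(self, record: DispensingRecord) -> bool:
        return self.drug_class(record.atc_code) is not None

    def followup_end(self, index_date: date) -> date:
        return index_date + timedelta(days=self.followup_days)

    @property
    def age_group_labels(self) -> tuple[str, ...]:
        e = self.age_group_edges
        return tuple(f"{a}-{b - 1}" for a, b in zip(e, e[1:]))

    def to_mapping(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, date):
                v = v.isoformat()
            elif isinstance(v, tuple) and v and isinstance(v[0], date):
                v = [d.isoformat() for d in v]
            elif isinstance(v, tuple):
                v = list(v)
            elif isinstance(v, Mapping):
                v = dict(v)
            out[f.name] = v
        return out

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_mapping(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> StudyConfig:
    """Load a YAML/JSON key-value document; unset keys take study defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ValueError("config must be a key-value document")
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return StudyConfig(**raw)


# ---------------------------------------------------------------------------
# Record I/O (CSV, UTF-8, ISO-8601 dates; optional gzip via file suffix)
# ---------------------------------------------------------------------------


def _parse_row(row: Mapping[str, str]) -> DispensingRecord:
    try:
        birth = date.fromisoformat(row["birth_date"])
        disp = date.fromisoformat(row["dispensation_date"])
    except ValueError as exc:
        raise ValueError(f"unparseable date: {exc}") from exc
    try:
        n_pack = int(row["n_packages"])
    except ValueError as exc:
        raise ValueError("unparseable package count") from exc
    try:
        ddd = float(row["ddd_per_package"])
    except ValueError as exc:
        raise ValueError("unparseable DDD per package") from exc
    rec = DispensingRecord(
        patient_id=row["patient_id"],
        birth_date=birth,
        sex=row["sex"],
        dispensation_date=disp,
        atc_code=row["atc_code"],
        drug_name=row["drug_name"],
        n_packages=n_pack,
        ddd_per_package=ddd,
    )
    rec.validate()
    return rec


def read_records(path, delimiter: str = ",") -> tuple[list[DispensingRecord], pd.DataFrame]:
    """Read and validate a dispensing table.

    Returns ``(records, rejects)`` where ``rejects`` is a report of malformed
    rows (0-based row index, patient id if readable, reason).  Malformed rows
    are never silently dropped: ``len(records) + len(rejects)`` equals the
    number of data rows in the file.  A missing mandatory column is a hard
    error naming the column.
    """
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in RECORD_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"missing mandatory column: {col}")
    records: list[DispensingRecord] = []
    rejects: list[dict] = []
    for i, row in enumerate(frame.to_dict("records")):
        try:
            records.append(_parse_row(row))
        except ValueError as exc:
            rejects.append(
                {"row": i, "patient_id": row.get("patient_id", ""), "reason": str(exc)}
            )
    return records, pd.DataFrame(rejects, columns=["row", "patient_id", "reason"])


def records_to_frame(records: Iterable[DispensingRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "birth_date": r.birth_date.isoformat(),
            "sex": r.sex,
            "dispensation_date": r.dispensation_date.isoformat(),
            "atc_code": r.atc_code,
            "drug_name": r.drug_name,
            "n_packages": r.n_packages,
            "ddd_per_package": r.ddd_per_package,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(records: Iterable[DispensingRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_deaths(path) -> list[DeathRecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in DEATH_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"missing mandatory column: {col}")
    return [
        DeathRecord(row["patient_id"], date.fromisoformat(row["death_date"]))
        for row in frame.to_dict("records")
    ]


def write_deaths(deaths: Iterable[DeathRecord], path) -> None:
    rows = [
        {"patient_id": d.patient_id, "death_date": d.death_date.isoformat()}
        for d in deaths
    ]
    pd.DataFrame(rows, columns=DEATH_COLUMNS).to_csv(path, index=False)
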