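from __future__ import annotations

from datetime import date

import pytest

from bph_persistence import StudyConfig
from bph_persistence.records_io import STUDY_DRUG_ATC, DispensingRecord
from bph_persistence.synthetic_data import SimulationParams, generate_dataset


def make_record(
    pid="P1",
    birth=date(1950, 1, 1),
    sex="M",
    on=date(2018, 4, 10),
    drug="tamsulosin",
    n_packages=1,
    ddd=30.0,
    atc=None,
):
    return DispensingRecord(
        patient_id=pid,
        birth_date=birth,
        sex=sex,
        dispensation_date=on,
        atc_code=atc or STUDY_DRUG_ATC.get(drug, "C09AA05"),
        drug_name=drug,
        n_packages=n_packages,
        ddd_per_package=ddd,
    )


@pytest.fixture(scope="session")
def config():
    return StudyConfig()


@pytest.fixture(scope="session")
def small_dataset(config):
    """Default-condition simulated dataset, shared across tests."""
    params = SimulationParams(n_patients=400, seed=7)
    return params, generate_dataset(params, config=config)
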