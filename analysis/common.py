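"""Shared plumbing for the numbered analysis drivers.

The simulated study data live under ``scratch/`` (regenerated on demand,
deterministic); the small result tables go to ``results/``.
"""

from __future__ import annotations

from pathlib import Path

from bph_persistence import StudyConfig, read_deaths, read_records
from bph_persistence.synthetic_data import (
    SimulationParams,
    generate_dataset,
    write_dataset,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "simulated_study"
RESULTS = ROOT / "results"

SEED = 20180401
N_PATIENTS = 5000


def study_config() -> StudyConfig:
    return StudyConfig()


def ensure_dataset():
    """Generate the simulated study population if absent; return its paths."""
    paths = {
        "records": SCRATCH / "records.csv",
        "deaths": SCRATCH / "deaths.csv",
        "truth": SCRATCH / "truth.csv",
    }
    if not all(p.exists() for p in paths.values()):
        params = SimulationParams(n_patients=N_PATIENTS, seed=SEED)
        data = generate_dataset(params, config=study_config())
        paths = write_dataset(*data, SCRATCH)
    return paths


def load_dataset():
    paths = ensure_dataset()
    records, rejects = read_records(paths["records"])
    assert rejects.empty
    deaths = read_deaths(paths["deaths"])
    return records, deaths
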