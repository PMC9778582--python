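"""Simulate the study population: 5000 men with dispensing histories for the
seven BPH/BPO study drugs, plus contaminant subpopulations exercising every
exclusion rule.  Writes records/deaths/truth CSVs under scratch/."""

from __future__ import annotations

import pandas as pd

from common import SEED, ensure_dataset

if __name__ == "__main__":
    paths = ensure_dataset()
    truth = pd.read_csv(paths["truth"])
    statuses = truth.groupby("patient_id")["status"].first().value_counts()
    print(f"simulated study population (seed {SEED}) written to {paths['records'].parent}")
    print(f"  dispensing records: {sum(1 for _ in open(paths['records'])) - 1}")
    print("  ground-truth patient statuses:")
    for status, n in statuses.items():
        print(f"    {status:>14}: {n}")
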