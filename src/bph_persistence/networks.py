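"""Drug-prescription networks and polypharmacy distributions by age.

An edge of the co-prescription network joins two study drugs and counts the
men prescribed both during their follow-up window (concurrent and sequential
use are not distinguished).  Polypharmacy tables give, per age group, the
distribution of the number of pharmacological classes (1 or 2) and of the
number of distinct drugs (1, 2, >= 3) prescribed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .cohort import CohortMember, percent, round_half_away
from .records_io import STUDY_DRUGS, StudyConfig


@dataclass
class DrugPairNetwork:
    """Undirected co-prescription graph over the study drugs."""

    nodes: dict[str, int]  # drug -> number of men exposed
    edges: dict[tuple[str, str], int]  # sorted pair -> number of men with both
    n_cohort: int

    @property
    def n_possible_pairs(self) -> int:
        k = len(self.nodes)
        return k * (k - 1) // 2

    @property
    def n_detected_pairs(self) -> int:
        return sum(1 for v in self.edges.values() if v > 0)

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "drug_a": a,
                "drug_b": b,
                "n": cnt,
                "pct": percent(cnt, self.n_cohort),
            }
            for (a, b), cnt in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["drug_a", "drug_b", "n", "pct"])


def build_pair_network(
    cohort: Sequence[CohortMember], drugs: Sequence[str] = STUDY_DRUGS
) -> DrugPairNetwork:
    """Count, for every unordered drug pair, the men prescribed both.

    Nodes with zero exposure are retained; an edge is counted once per member
    whose ``drugs_prescribed`` set contains both endpoints.
    """
    nodes = {d: 0 for d in drugs}
    edges = {tuple(sorted(p)): 0 for p in combinations(drugs, 2)}
    for m in cohort:
        held = sorted(d for d in m.drugs_prescribed if d in nodes)
        for d in held:
            nodes[d] += 1
        for pair in combinations(held, 2):
            edges[pair] += 1
    return DrugPairNetwork(nodes=nodes, edges=edges, n_cohort=len(cohort))


@dataclass
class PolypharmacyTable:
    """Per-age-group distributions of class counts and drug counts."""

    classes: pd.DataFrame  # columns: age_group, n, n_1, n_2, pct_1, pct_2
    drugs: pd.DataFrame  # columns: age_group, n, n_1, n_2, n_3plus, pct_...


def _bucket_counts(values: list[int], buckets: Sequence[tuple[str, int, float]]) -> dict:
    out = {}
    for name, lo, hi in buckets:
        out[name] = sum(1 for v in values if lo <= v <= hi)
    return out


def polypharmacy_by_age(
    cohort: Sequence[CohortMember], config: StudyConfig
) -> PolypharmacyTable:
    """Distributions of |classes prescribed| and |drugs prescribed| per age group."""
    groups = [g for g in config.age_group_labels] + (
        ["out_of_range"] if any(m.age_group == "out_of_range" for m in cohort) else []
    )
    class_rows, drug_rows = [], []
    for g in groups:
        members = [m for m in cohort if m.age_group == g]
        if not members:
            continue
        n = len(members)
        ncls = [len(m.classes_prescribed) for m in members]
        cb = _bucket_counts(ncls, [("1", 1, 1), ("2", 2, float("inf"))])
        class_rows.append(
            {
                "age_group": g,
                "n": n,
                "n_1": cb["1"],
                "n_2": cb["2"],
                "pct_1": percent(cb["1"], n),
                "pct_2": percent(cb["2"], n),
            }
        )
        ndr = [len(m.drugs_prescribed) for m in members]
        db = _bucket_counts(ndr, [("1", 1, 1), ("2", 2, 2), ("3+", 3, float("inf"))])
        drug_rows.append(
            {
                "age_group": g,
                "n": n,
                "n_1": db["1"],
                "n_2": db["2"],
                "n_3plus": db["3+"],
                "pct_1": percent(db["1"], n),
                "pct_2": percent(db["2"], n),
                "pct_3plus": percent(db["3+"], n),
            }
        )
    return PolypharmacyTable(
        classes=pd.DataFrame(class_rows), drugs=pd.DataFrame(drug_rows)
    )


def drugs_within_class_by_age(
    cohort: Sequence[CohortMember], config: StudyConfig, cls: str
) -> pd.DataFrame:
    """Among men exposed to ``cls``, distribution of the number of distinct
    drugs of that class prescribed, per age group."""
    class_of = {name: config.drug_class(atc) for name, atc in _drug_atc(config)}
    rows = []
    for g in config.age_group_labels:
        members = [
            m
            for m in cohort
            if m.age_group == g and cls in m.classes_prescribed
        ]
        if not members:
            continue
        n = len(members)
        counts = [
            sum(1 for d in m.drugs_prescribed if class_of.get(d) == cls)
            for m in members
        ]
        b = _bucket_counts(counts, [("1", 1, 1), ("2", 2, 2), ("3+", 3, float("inf"))])
        rows.append(
            {
                "age_group": g,
                "n": n,
                "n_1": b["1"],
                "n_2": b["2"],
                "n_3plus": b["3+"],
                "pct_1": percent(b["1"], n),
                "pct_2": percent(b["2"], n),
                "pct_3plus": percent(b["3+"], n),
            }
        )
    return pd.DataFrame(rows)


def _drug_atc(config: StudyConfig):
    from .records_io import STUDY_DRUG_ATC

    return STUDY_DRUG_ATC.items()


def single_drug_share_young_old(
    cohort: Sequence[CohortMember],
    config: StudyConfig,
    cls: str,
    mode: str = "mean",
) -> dict[str, float]:
    """Percentage of men prescribed exactly one drug of ``cls`` (among men
    exposed to that class), aggregated over the young (< cut) and old
    (>= cut) age groups.

    ``mode="mean"`` takes the arithmetic mean of the per-age-group
    percentages; ``mode="pooled"`` pools the members directly.
    """
    table = drugs_within_class_by_age(cohort, config, cls)
    if table.empty:
        return {"young": float("nan"), "old": float("nan")}
    young_groups = [
        f"{a}-{b - 1}"
        for a, b in zip(config.age_group_edges, config.age_group_edges[1:])
        if b <= config.young_old_cut
    ]
    out = {}
    for side, predicate in (
        ("young", lambda g: g in young_groups),
        ("old", lambda g: g not in young_groups),
    ):
        sub = table[table["age_group"].map(predicate)]
        if sub.empty:
            out[side] = float("nan")
        elif mode == "mean":
            out[side] = round_half_away(float(sub["pct_1"].mean()), 1)
        elif mode == "pooled":
            out[side] = percent(int(sub["n_1"].sum()), int(sub["n"].sum()))
        else:
            raise ValueError("mode must be 'mean' or 'pooled'")
    return out
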