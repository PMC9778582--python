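"""Pipeline orchestration: records -> cohort -> episodes -> survival -> networks.

``analyze`` runs the full analysis in memory; ``run_pipeline`` wraps it with
file I/O and writes a reproducible report bundle (CSV tables keyed by the
configuration hash, with a run log).  Re-running with the same inputs and
configuration reproduces byte-identical CSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import (
    CohortMember,
    ExclusionLedger,
    select_cohort,
    summarize_cohort,
    wilcoxon_rank_sum,
)
from .episodes import (
    LEVEL_CLASS,
    LEVEL_DRUG,
    SurvivalObservation,
    build_episodes,
    spans_from_records,
    time_to_discontinuation,
)
from .networks import (
    build_pair_network,
    drugs_within_class_by_age,
    polypharmacy_by_age,
    single_drug_share_young_old,
)
from .records_io import (
    AB,
    FIVE_ARI,
    DeathRecord,
    DispensingRecord,
    StudyConfig,
    load_config,
    read_deaths,
    read_records,
)
from .survival import KMCurve, format_p, km_estimate, km_median, logrank_test, survival_at


def build_observations(
    records: Iterable[DispensingRecord],
    cohort: Sequence[CohortMember],
    config: StudyConfig,
    level: str,
) -> dict[str, list[SurvivalObservation]]:
    """Per-key survival observations for every cohort member.

    At drug level each member contributes one observation per drug he filled
    during follow-up (clock starting at that drug's first fill); at class
    level one observation per class.  Switchers are not censored at switch.
    """
    by_patient: dict[str, list[DispensingRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)

    out: dict[str, list[SurvivalObservation]] = {}
    for m in cohort:
        fills = [
            r
            for r in by_patient.get(m.patient_id, ())
            if config.is_study_drug(r)
            and m.index_date <= r.dispensation_date < m.followup_end
        ]
        spans = spans_from_records(fills, config, level)
        episodes = build_episodes(
            spans,
            level,
            config,
            patient_id=m.patient_id,
            death_date=m.death_date,
            followup_end=m.followup_end,
        )
        by_key: dict[str, list] = {}
        for ep in episodes:
            by_key.setdefault(ep.key, []).append(ep)
        for key, eps in by_key.items():
            out.setdefault(key, []).append(time_to_discontinuation(eps, m, config))
    return out


def _curve_frame(curve: KMCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": curve.event_times,
            "at_risk": curve.at_risk.astype(int),
            "events": curve.deaths.astype(int),
            "survival": curve.survival,
            "ci_lower": curve.ci_lower,
            "ci_upper": curve.ci_upper,
        }
    )


@dataclass
class AnalysisResult:
    """In-memory results of one full pipeline run."""

    config: StudyConfig
    cohort: list[CohortMember]
    ledger: ExclusionLedger
    summaries: dict[str, pd.DataFrame]
    drug_observations: dict[str, list[SurvivalObservation]]
    class_observations: dict[str, list[SurvivalObservation]]
    km_curves: dict[str, KMCurve]
    persistence_table: pd.DataFrame
    median_table: pd.DataFrame
    logrank_table: pd.DataFrame
    wilcoxon_age: dict[str, float] | None
    network: object
    polypharmacy: object
    single_drug_young_old: dict[str, dict[str, float]]


def analyze(
    records: Iterable[DispensingRecord],
    deaths: Iterable[DeathRecord] | None,
    config: StudyConfig,
) -> AnalysisResult:
    records = list(records)
    cohort, ledger = select_cohort(records, deaths, config)
    if not cohort:
        return AnalysisResult(
            config=config,
            cohort=[],
            ledger=ledger,
            summaries={},
            drug_observations={},
            class_observations={},
            km_curves={},
            persistence_table=pd.DataFrame(),
            median_table=pd.DataFrame(),
            logrank_table=pd.DataFrame(),
            wilcoxon_age=None,
            network=None,
            polypharmacy=None,
            single_drug_young_old={},
        )

    summaries = summarize_cohort(cohort)

    drug_obs = build_observations(records, cohort, config, LEVEL_DRUG)
    class_obs = build_observations(records, cohort, config, LEVEL_CLASS)

    curves: dict[str, KMCurve] = {}
    for drug, obs in sorted(drug_obs.items()):
        curves[f"drug:{drug}"] = km_estimate(obs, ci_method=config.ci_method)
    for cls, obs in sorted(class_obs.items()):
        curves[f"class:{cls}"] = km_estimate(obs, ci_method=config.ci_method)
        for side in ("young", "old"):
            sub = [o for o in obs if o.young_old == side]
            if sub:
                curves[f"class:{cls}|{side}"] = km_estimate(sub, ci_method=config.ci_method)

    pers_rows, med_rows = [], []
    for key, curve in curves.items():
        at365 = survival_at(curve, config.followup_days)
        med = km_median(curve)
        pers_rows.append(
            {
                "key": key,
                "n": curve.n_total,
                "n_events": curve.n_events,
                "pct_persistent": at365["pct"],
                "pct_ci_lower": at365["pct_ci"][0],
                "pct_ci_upper": at365["pct_ci"][1],
            }
        )
        med_rows.append(
            {
                "key": key,
                "median_days": "NR" if med.median_days is None else med.median_days,
                "ci_lower": "NR" if med.ci_lower is None else med.ci_lower,
                "ci_upper": "NR" if med.ci_upper is None else med.ci_upper,
            }
        )
    persistence_table = pd.DataFrame(pers_rows)
    median_table = pd.DataFrame(med_rows)

    lr_rows = []

    def _logrank(name: str, groups: Mapping[str, list[SurvivalObservation]]):
        groups = {k: v for k, v in groups.items() if v}
        if len(groups) < 2:
            return
        res = logrank_test(groups)
        lr_rows.append(
            {
                "comparison": name,
                "chi_square": res.chi_square,
                "df": res.df,
                "p_value": res.p_value,
                "p_display": format_p(res.p_value),
            }
        )

    class_of_drug = {}
    for drug in drug_obs:
        # recover the class from any record of that drug
        atc = next(r.atc_code for r in records if r.drug_name == drug)
        class_of_drug[drug] = config.drug_class(atc)
    for cls in (AB, FIVE_ARI):
        within = {d: o for d, o in drug_obs.items() if class_of_drug.get(d) == cls}
        _logrank(f"drugs_within_{cls}", within)
        if cls in class_obs:
            strata = {
                side: [o for o in class_obs[cls] if o.young_old == side]
                for side in ("young", "old")
            }
            _logrank(f"{cls}_young_vs_old", strata)
    logrank_table = pd.DataFrame(lr_rows)

    ages_ab = [m.age_at_reference for m in cohort if AB in m.classes_prescribed]
    ages_5ari = [m.age_at_reference for m in cohort if FIVE_ARI in m.classes_prescribed]
    wilcoxon_age = (
        wilcoxon_rank_sum(ages_ab, ages_5ari) if ages_ab and ages_5ari else None
    )

    network = build_pair_network(cohort)
    poly = polypharmacy_by_age(cohort, config)
    single = {
        cls: single_drug_share_young_old(cohort, config, cls, mode="mean")
        for cls in (AB, FIVE_ARI)
    }

    return AnalysisResult(
        config=config,
        cohort=cohort,
        ledger=ledger,
        summaries=summaries,
        drug_observations=drug_obs,
        class_observations=class_obs,
        km_curves=curves,
        persistence_table=persistence_table,
        median_table=median_table,
        logrank_table=logrank_table,
        wilcoxon_age=wilcoxon_age,
        network=network,
        polypharmacy=poly,
        single_drug_young_old=single,
    )


@dataclass
class ReportBundle:
    out_dir: Path
    config_hash: str
    result: AnalysisResult
    paths: dict[str, Path] = field(default_factory=dict)
    warning: str | None = None


def _safe(key: str) -> str:
    return key.replace(":", "_").replace("|", "_")


def run_pipeline(
    records_path,
    deaths_path,
    config_path,
    out_dir,
    *,
    make_plots: bool = False,
    overrides: Mapping | None = None,
) -> ReportBundle:
    """Execute all stages from files and write the report bundle.

    ``overrides`` patches individual config fields (CLI flags).  An empty
    eligible cohort produces a ledger-only bundle with a warning.
    """
    config = load_config(config_path) if config_path else StudyConfig()
    if overrides:
        import dataclasses

        config = dataclasses.replace(config, **dict(overrides))
    records, rejects = read_records(records_path)
    deaths = read_deaths(deaths_path) if deaths_path else []

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out, config_hash=config.config_hash(), result=None)

    import yaml

    (out / "config.yaml").write_text(
        yaml.safe_dump(config.to_mapping(), sort_keys=True)
    )
    rejects.to_csv(out / "rejects.csv", index=False)

    result = analyze(records, deaths, config)
    bundle.result = result
    result.ledger.to_frame().to_csv(out / "exclusion_ledger.csv", index=False)
    bundle.paths["ledger"] = out / "exclusion_ledger.csv"

    log_lines = [
        f"config_hash: {config.config_hash()}",
        f"records_read: {len(records)}",
        f"records_rejected: {len(rejects)}",
        f"patients_with_study_drug: {result.ledger.n_patients}",
        f"cohort_size: {len(result.cohort)}",
    ]

    if not result.cohort:
        bundle.warning = "empty eligible cohort; ledger-only report"
        log_lines.append("warning: empty eligible cohort")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        return bundle

    for name, frame in result.summaries.items():
        frame.to_csv(out / f"table1_{name}.csv", index=False)
    result.persistence_table.to_csv(out / "table2_persistence.csv", index=False)
    result.median_table.to_csv(out / "medians.csv", index=False)
    result.logrank_table.to_csv(out / "logrank.csv", index=False)
    if result.wilcoxon_age is not None:
        pd.DataFrame([result.wilcoxon_age]).to_csv(
            out / "table3_wilcoxon_age.csv", index=False
        )
    result.network.to_edge_frame().to_csv(out / "network_edges.csv", index=False)
    result.polypharmacy.classes.to_csv(out / "polypharmacy_classes.csv", index=False)
    result.polypharmacy.drugs.to_csv(out / "polypharmacy_drugs.csv", index=False)
    for cls in (AB, FIVE_ARI):
        drugs_within_class_by_age(result.cohort, config, cls).to_csv(
            out / f"polypharmacy_drugs_{_safe(cls)}.csv", index=False
        )

    curves_dir = out / "km_curves"
    curves_dir.mkdir(exist_ok=True)
    for key, curve in result.km_curves.items():
        _curve_frame(curve).to_csv(curves_dir / f"km_{_safe(key)}.csv", index=False)

    if make_plots:
        _plot_curves(result, out)

    log_lines += [
        f"drug_level_keys: {len(result.drug_observations)}",
        f"class_level_keys: {len(result.class_observations)}",
        f"network_pairs_detected: {result.network.n_detected_pairs}"
        f"/{result.network.n_possible_pairs}",
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return bundle


def _plot_curves(result: AnalysisResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    for prefix, title in (("drug:", "per-drug"), ("class:", "per-class")):
        fig, ax = plt.subplots(figsize=(7, 5))
        for key, curve in result.km_curves.items():
            if not key.startswith(prefix) or "|" in key:
                continue
            ax.step(
                [0, *curve.event_times],
                [1.0, *curve.survival],
                where="post",
                label=key.split(":", 1)[1],
            )
        ax.set_xlabel("days since index date")
        ax.set_ylabel("proportion persistent")
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=8)
        fig.savefig(fig_dir / f"km_{title.replace('-', '_')}.png", dpi=120)
        plt.close(fig)
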