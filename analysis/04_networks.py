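"""Drug-prescription network and polypharmacy-by-age distributions: which
drug pairs reach the same men, and how class/drug counts shift with age."""

from __future__ import annotations

from common import RESULTS, load_dataset, study_config

from bph_persistence import (
    build_pair_network,
    polypharmacy_by_age,
    select_cohort,
    single_drug_share_young_old,
)
from bph_persistence.networks import drugs_within_class_by_age

if __name__ == "__main__":
    config = study_config()
    records, deaths = load_dataset()
    cohort, _ = select_cohort(records, deaths, config)
    RESULTS.mkdir(exist_ok=True)

    net = build_pair_network(cohort)
    net.to_edge_frame().to_csv(RESULTS / "network_edges.csv", index=False)
    poly = polypharmacy_by_age(cohort, config)
    poly.classes.to_csv(RESULTS / "polypharmacy_classes_by_age.csv", index=False)
    poly.drugs.to_csv(RESULTS / "polypharmacy_drugs_by_age.csv", index=False)
    for cls in ("AB", "5ARI"):
        drugs_within_class_by_age(cohort, config, cls).to_csv(
            RESULTS / f"polypharmacy_{cls}_drugs_by_age.csv", index=False
        )

    print(f"detected {net.n_detected_pairs} of {net.n_possible_pairs} possible drug pairs")
    edges = net.to_edge_frame().sort_values("n", ascending=False)
    print("most common pairs:")
    print(edges.head(5).to_string(index=False))
    for cls in ("AB", "5ARI"):
        share = single_drug_share_young_old(cohort, config, cls, mode="mean")
        print(
            f"single-{cls} share (arithmetic mean of age-group percentages): "
            f"young {share['young']}%, old {share['old']}%"
        )
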