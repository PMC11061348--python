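"""Triage false positives and build the screening prioritization report.

Reads results/predictions.csv, assigns every false positive a triage
category (antagonist flag -> below-TP-quartile -> low assay count ->
residual), and ranks subset-positive chemicals by assay support and AUC,
marking clusters that contain positives and surfacing their negative
members as cluster-rescued screening candidates.
"""

import argparse
from pathlib import Path

import pandas as pd

from erconcord.data_model import ClusterAssignment
from erconcord.pipeline import load_config
from erconcord.triage import TriageConfig, prioritization_list, triage_false_positives

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    cfg = load_config(overrides={"seed": args.seed})

    preds = pd.read_csv(ROOT / "results" / "predictions.csv").set_index("chem_id")
    cl = pd.read_csv(ROOT / "results" / "clusters.csv")
    labels = dict(zip(cl["chem_id"], cl["cluster_id"]))
    labels.update(dict(zip(preds.index, preds["cluster_id"])))
    parent = ClusterAssignment(
        dict(zip(cl["chem_id"], cl["cluster_id"])),
        cut_height=float(cl["cut_height"].iloc[0]),
        linkage_variant=str(cl["linkage_variant"].iloc[0]),
    )
    assign = ClusterAssignment.referencing(
        {c: int(labels[c]) for c in preds.index}, parent
    )

    tcfg = TriageConfig(
        tp_quantile=cfg["tp_quantile"],
        min_active_assays=cfg["min_active_assays"],
        activity_threshold=cfg["activity_threshold"],
    )
    report = triage_false_positives(preds, tcfg)
    print(f"TP subset-AUC lower quartile: {report.tp_quantile_value:.3f}")
    print(f"{report.n_false_positives} false positives by category:")
    for cat, n in report.counts.items():
        print(f"  {cat:>24}: {n}")

    ranked, enrichment, rescued = prioritization_list(preds, assign, tcfg)
    out = ROOT / "results"
    report.per_chemical.rename_axis("chem_id").reset_index().to_csv(out / "triage.csv", index=False)
    ranked.to_csv(out / "priority.csv", index=False)
    enrichment.to_csv(out / "cluster_enrichment.csv", index=False)
    rescued.to_csv(out / "cluster_rescued.csv", index=False)
    n_marked = int(enrichment["marked"].sum())
    print(
        f"{len(ranked)} positives ranked; {n_marked} clusters marked as "
        f"containing activity; {len(rescued)} negatives rescued for screening"
    )


if __name__ == "__main__":
    main()
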