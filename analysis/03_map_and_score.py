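"""Map tested chemicals into clusters by KNN and score the subset model.

Reads results/inputs/ and results/clusters.csv, selects k on an 80/20 split
of the labelled universe, maps the tested set, scores the 4-assay subset
model against the full-model reference, and writes the per-chemical
predictions and per-cluster concordance statistics.
"""

import argparse
from pathlib import Path

import pandas as pd

from erconcord.concordance import cluster_confusion, global_discrepancy_table, partition_by_prevalence
from erconcord.data_model import (
    ClusterAssignment,
    join_datasets,
    load_assay_aucs,
    load_chemicals,
    load_fingerprints,
    load_full_model,
    load_model_spec,
)
from erconcord.er_models import score_chemicals
from erconcord.knn_map import coverage_report, knn_assign, select_k
from erconcord.pipeline import load_config

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    cfg = load_config(overrides={"seed": args.seed})

    inp = ROOT / "results" / "inputs"
    chems = load_chemicals(inp / "chemicals.csv")
    fps = load_fingerprints(inp / "fingerprints.csv")
    aucs = load_assay_aucs(inp / "assay_aucs.csv")
    spec = load_model_spec(inp / "model_spec.yaml")
    ref = load_full_model(inp / "full_model.csv")
    bundle = join_datasets(chems, fps, aucs, ref)

    cl = pd.read_csv(ROOT / "results" / "clusters.csv")
    assign = ClusterAssignment(
        dict(zip(cl["chem_id"], cl["cluster_id"])),
        cut_height=float(cl["cut_height"].iloc[0]),
        linkage_variant=str(cl["linkage_variant"].iloc[0]),
    )

    univ_fps = fps.subset(bundle.universe_ids)
    ksel = select_k(univ_fps, assign, seed=cfg["seed"])
    print(f"k selection accuracies: {ksel.accuracy_by_k} -> k={ksel.chosen_k}")

    tested_fps = fps.subset(bundle.tested_ids)
    tested_assign = knn_assign(univ_fps, assign, tested_fps, ksel.chosen_k)
    coverage = coverage_report(assign, tested_assign)
    same = sum(1 for c in bundle.overlap_ids if tested_assign.labels[c] == assign.labels[c])
    print(
        f"{same}/{len(bundle.overlap_ids)} chemicals in both sets mapped back to "
        f"their own cluster; {coverage['n_clusters_with_tested']} clusters reached"
    )

    preds, excluded = score_chemicals(aucs, spec, ref, bundle.tested_ids)
    stats, below = cluster_confusion(preds, tested_assign, cfg["min_cluster_n"])
    disc = global_discrepancy_table(preds)
    print(
        f"scored {len(preds)} chemicals ({len(excluded)} excluded): "
        f"TP={disc['tp']} FP={disc['fp']} TN={disc['tn']} FN={disc['fn']}"
    )
    print(
        f"median FP subset AUC {disc['median_fp_subset_auc']:.3f} "
        f"vs full {disc['median_fp_full_auc']:.3f}"
    )

    out = ROOT / "results"
    preds.rename_axis("chem_id").reset_index().assign(
        cluster_id=lambda df: df["chem_id"].map(tested_assign.labels)
    ).to_csv(out / "predictions.csv", index=False)
    stats.to_csv(out / "cluster_stats.csv", index=False)
    partition_by_prevalence(stats).to_csv(out / "partition.csv", index=False)
    print(partition_by_prevalence(stats).to_string(index=False))


if __name__ == "__main__":
    main()
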