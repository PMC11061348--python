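"""Per-cluster confusion matrices and concordance statistics.

For each cluster with at least ``min_cluster_n`` scored chemicals a 2x2
confusion matrix (subset call vs full-model call) is tallied and summarized
with sensitivity, specificity, accuracy, balanced accuracy, PPV, NPV and
prevalence, plus mean subset/full AUC and the mean and SD of their
difference.  Ratios with a zero denominator are reported as NaN, never as 0
or 1, and NaN components propagate into balanced accuracy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import ClusterAssignment

__all__ = [
    "cluster_confusion",
    "partition_by_prevalence",
    "global_discrepancy_table",
]

STAT_COLUMNS = [
    "cluster_id", "n", "tp", "fp", "tn", "fn",
    "sensitivity", "specificity", "accuracy", "balanced_accuracy",
    "ppv", "npv", "prevalence",
    "mean_subset_auc", "mean_full_auc", "mean_auc_diff", "sd_auc_diff",
]


def _safe_ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def _stats_row(cluster_id: int, grp: pd.DataFrame) -> dict:
    counts = grp["confusion_label"].value_counts()
    tp = int(counts.get("TP", 0))
    fp = int(counts.get("FP", 0))
    tn = int(counts.get("TN", 0))
    fn = int(counts.get("FN", 0))
    n = len(grp)
    sens = _safe_ratio(tp, tp + fn)
    spec = _safe_ratio(tn, tn + fp)
    diff = grp["subset_auc_med"] - grp["full_auc"]
    return {
        "cluster_id": cluster_id,
        "n": n,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": (tp + tn) / n,
        # undefined if either component is undefined (a half-informed mean
        # would silently overstate performance in one-class clusters)
        "balanced_accuracy": (sens + spec) / 2,
        "ppv": _safe_ratio(tp, tp + fp),
        "npv": _safe_ratio(tn, tn + fn),
        "prevalence": (tp + fn) / n,
        "mean_subset_auc": float(grp["subset_auc_med"].mean()),
        "mean_full_auc": float(grp["full_auc"].mean()),
        "mean_auc_diff": float(diff.mean()),
        "sd_auc_diff": float(diff.std(ddof=1)) if n > 1 else float("nan"),
    }


def cluster_confusion(
    preds: pd.DataFrame,
    assign: ClusterAssignment,
    min_cluster_n: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster confusion statistics for clusters of size >= min_cluster_n.

    Returns ``(stats, below_floor)``: one row per retained cluster, and the
    per-chemical listing of chemicals in clusters below the size floor
    (columns chem_id, cluster_id, confusion_label).  A predicted chemical
    with no cluster assignment is a hard error.
    """
    unassigned = [c for c in preds.index if c not in assign.labels]
    if unassigned:
        raise ValueError(f"predicted chemicals without a cluster: {unassigned[:5]}")
    work = preds.copy()
    work["cluster_id"] = [assign.labels[c] for c in preds.index]

    rows, small = [], []
    for cluster_id, grp in work.groupby("cluster_id", sort=True):
        if len(grp) >= min_cluster_n:
            rows.append(_stats_row(int(cluster_id), grp))
        else:
            for chem_id, row in grp.iterrows():
                small.append(
                    {"chem_id": chem_id, "cluster_id": int(cluster_id),
                     "confusion_label": row["confusion_label"]}
                )
    stats = pd.DataFrame(rows, columns=STAT_COLUMNS)
    below = pd.DataFrame(small, columns=["chem_id", "cluster_id", "confusion_label"])
    return stats, below


def partition_by_prevalence(stats: pd.DataFrame) -> pd.DataFrame:
    """Split clusters by reference-call prevalence, the triage entry point.

    Groups: prevalence 0 split into perfect-match (specificity 1, the subset
    model also calls everything inactive) vs containing >=1 false positive;
    mixed prevalence (0 < p < 1); and prevalence 1.  One row per group with
    cluster and chemical counts.
    """
    groups = {
        "prev0_perfect": (stats["prevalence"] == 0) & (stats["fp"] == 0),
        "prev0_with_fp": (stats["prevalence"] == 0) & (stats["fp"] > 0),
        "mixed": (stats["prevalence"] > 0) & (stats["prevalence"] < 1),
        "prev1": stats["prevalence"] == 1,
    }
    rows = []
    for name, mask in groups.items():
        sub = stats[mask]
        rows.append(
            {
                "group": name,
                "n_clusters": len(sub),
                "n_chemicals": int(sub["n"].sum()),
                "n_fp": int(sub["fp"].sum()),
                "n_fn": int(sub["fn"].sum()),
            }
        )
    out = pd.DataFrame(rows)
    assert out["n_clusters"].sum() == len(stats)
    return out


def global_discrepancy_table(preds: pd.DataFrame) -> dict:
    """Dataset-level confusion counts and the discrepancy summary.

    Reports overall TP/FP/TN/FN counts, the median subset and full AUC among
    false positives (NaN when there are none), and the false-negative
    chemicals with both model scores.
    """
    counts = preds["confusion_label"].value_counts()
    fp = preds[preds["confusion_label"] == "FP"]
    fn = preds[preds["confusion_label"] == "FN"]
    return {
        "n": len(preds),
        "tp": int(counts.get("TP", 0)),
        "fp": int(counts.get("FP", 0)),
        "tn": int(counts.get("TN", 0)),
        "fn": int(counts.get("FN", 0)),
        "n_discrepant": int(counts.get("FP", 0) + counts.get("FN", 0)),
        "median_fp_subset_auc": float(fp["subset_auc_med"].median()) if len(fp) else float("nan"),
        "median_fp_full_auc": float(fp["full_auc"].median()) if len(fp) else float("nan"),
        "fn_chemicals": fn[["subset_auc_med", "full_auc"]].rename_axis("chem_id").reset_index(),
    }
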