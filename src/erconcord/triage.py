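"""False-positive triage cascade and screening prioritization.

False positives (subset-model active, full-model inactive) are assigned to
the first matching category in a fixed order:

1. ``antagonist_flagged`` - the full pathway model called the chemical an
   antagonist; a subset battery without antagonist assays cannot move such
   chemicals out of the agonist mode, so these are expected hits.
2. ``below_tp_quartile`` - subset AUC strictly below the lower quantile
   (default 25th percentile) of the true positives' subset AUCs; AUC-ranked
   screening would reach most true positives first.
3. ``low_assay_count`` - active in fewer than ``min_active_assays`` of the
   model's component assays (default 3 of 4); consistent multi-assay
   activity is demanded of a credible agonist signal.
4. ``residual_high_priority`` - everything else: false positives that no
   cheap rule removes.

Prioritization ranks subset-positive chemicals by assay support then AUC,
and marks clusters containing positives so their negative members can be
surfaced as cluster-rescued screening candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ClusterAssignment

__all__ = [
    "TriageConfig",
    "TriageReport",
    "tp_auc_quantile",
    "ci_overlaps_threshold",
    "triage_false_positives",
    "prioritization_list",
]

CATEGORIES = [
    "antagonist_flagged",
    "below_tp_quartile",
    "low_assay_count",
    "residual_high_priority",
]


@dataclass
class TriageConfig:
    tp_quantile: float = 0.25
    min_active_assays: int = 3
    activity_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.tp_quantile < 1:
            raise ValueError("tp_quantile must lie strictly between 0 and 1")
        if self.min_active_assays < 1:
            raise ValueError("min_active_assays must be >= 1")


@dataclass
class TriageReport:
    per_chemical: pd.DataFrame  # index chem_id; category, subset_auc_med, n_active_assays, ci_overlaps_threshold
    counts: dict[str, int]
    tp_quantile_value: float
    config: TriageConfig

    @property
    def n_false_positives(self) -> int:
        return len(self.per_chemical)


def tp_auc_quantile(preds: pd.DataFrame, q: float = 0.25) -> float:
    """Linear-interpolation quantile of subset AUC over the true positives."""
    tp = preds.loc[preds["confusion_label"] == "TP", "subset_auc_med"]
    if tp.empty:
        raise ValueError("no true-positive chemicals: quantile undefined")
    return float(np.quantile(tp.to_numpy(dtype=float), q, method="linear"))


def ci_overlaps_threshold(pred: pd.Series, threshold: float = 0.1) -> bool:
    """True iff the subset-model CI (or the full-model CI, when present)
    contains the activity threshold; both intervals are closed."""
    if pred["subset_auc_lo"] <= threshold <= pred["subset_auc_hi"]:
        return True
    if "full_lo" in pred.index and "full_hi" in pred.index:
        lo, hi = pred["full_lo"], pred["full_hi"]
        if pd.notna(lo) and pd.notna(hi) and lo <= threshold <= hi:
            return True
    return False


def triage_false_positives(preds: pd.DataFrame, cfg: TriageConfig | None = None) -> TriageReport:
    """Assign every false positive its first matching triage category."""
    cfg = cfg or TriageConfig()
    quartile = tp_auc_quantile(preds, cfg.tp_quantile)
    fp = preds[preds["confusion_label"] == "FP"]

    def _categorize(row: pd.Series) -> str:
        if row["antagonist_flag"]:
            return "antagonist_flagged"
        if row["subset_auc_med"] < quartile:
            return "below_tp_quartile"
        if row["n_active_assays"] < cfg.min_active_assays:
            return "low_assay_count"
        return "residual_high_priority"

    per_chem = pd.DataFrame(index=fp.index.rename("chem_id"))
    per_chem["category"] = [_categorize(row) for _, row in fp.iterrows()]
    per_chem["subset_auc_med"] = fp["subset_auc_med"]
    per_chem["n_active_assays"] = fp["n_active_assays"]
    per_chem["ci_overlaps_threshold"] = [
        ci_overlaps_threshold(row, cfg.activity_threshold) for _, row in fp.iterrows()
    ]
    counts = {cat: int((per_chem["category"] == cat).sum()) for cat in CATEGORIES}
    assert sum(counts.values()) == len(per_chem)
    return TriageReport(per_chemical=per_chem, counts=counts, tp_quantile_value=quartile, config=cfg)


def prioritization_list(
    preds: pd.DataFrame,
    assign: ClusterAssignment,
    cfg: TriageConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Rank subset-positive chemicals and surface cluster-rescued negatives.

    Returns ``(ranked, enrichment, rescued)``:

    * ``ranked`` - subset-positive chemicals, chemicals meeting the
      min-active-assay support first, then by subset AUC descending, ties by
      chem_id;
    * ``enrichment`` - per cluster: tested count, positives, positive
      fraction, and a mark for clusters containing >=1 positive;
    * ``rescued`` - subset-negative chemicals in marked clusters (screening
      candidates justified by their structural neighbours' activity).
    """
    cfg = cfg or TriageConfig()
    unassigned = [c for c in preds.index if c not in assign.labels]
    if unassigned:
        raise ValueError(f"chemicals without a cluster: {unassigned[:5]}")
    work = preds.copy()
    work["cluster_id"] = [assign.labels[c] for c in work.index]

    pos = work[work["subset_call"] == 1].copy()
    pos["well_supported"] = pos["n_active_assays"] >= cfg.min_active_assays
    ranked = (
        pos.rename_axis("chem_id")
        .reset_index()
        .sort_values(
            ["well_supported", "subset_auc_med", "chem_id"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        .reset_index(drop=True)
    )[["chem_id", "cluster_id", "subset_auc_med", "n_active_assays", "well_supported", "confusion_label"]]

    grp = work.groupby("cluster_id")
    enrichment = pd.DataFrame(
        {
            "n_tested": grp.size(),
            "n_positive": grp["subset_call"].sum().astype(int),
        }
    )
    enrichment["positive_fraction"] = enrichment["n_positive"] / enrichment["n_tested"]
    enrichment["marked"] = enrichment["n_positive"] > 0
    enrichment = enrichment.rename_axis("cluster_id").reset_index()

    marked = set(enrichment.loc[enrichment["marked"], "cluster_id"])
    rescued = (
        work[(work["subset_call"] == 0) & work["cluster_id"].isin(marked)]
        .rename_axis("chem_id")
        .reset_index()
    )[["chem_id", "cluster_id", "subset_auc_med", "full_auc", "confusion_label"]]
    return ranked, enrichment, rescued
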