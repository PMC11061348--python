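"""Subset-model agonist scores, activity calls, and confusion labels.

The reduced (subset) agonist model scores a chemical as the weighted mean of
its per-assay AUC values over the model's assays.  AUC here is the pathway
model's area-under-curve activity score in [0, 1] (not a ROC area).  Scores
are dichotomized at a threshold (default 0.1, call active iff AUC >= 0.1)
and compared against the full-model reference call, which is treated as
truth: TP = active in both, FP = active only in the subset model, FN =
active only in the full model, TN = inactive in both.

Confidence-interval scores are obtained by applying the same weighted mean
to the lower/upper 95% CI chemical-assay AUC matrices.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_model import AssayAUCTable, FullModelReference, ModelSpec

logger = logging.getLogger("erconcord")

__all__ = [
    "subset_auc",
    "dichotomize",
    "count_active_assays",
    "label_confusion",
    "score_chemicals",
]

CONFUSION = {(1, 1): "TP", (0, 0): "TN", (0, 1): "FP", (1, 0): "FN"}


def subset_auc(assay_aucs: np.ndarray, spec: ModelSpec) -> float:
    """Weighted mean AUC over the model's assays.

    With ``normalize_weights`` (default) the score is sum(w*auc)/sum(w), so
    it stays on the [0, 1] AUC scale and equals the plain mean under equal
    weights; otherwise the raw weighted sum is returned.
    """
    vals = np.asarray(assay_aucs, dtype=float)
    if vals.shape != (len(spec.assay_names),):
        raise ValueError(f"expected {len(spec.assay_names)} assay values, got {vals.shape}")
    if np.isnan(vals).any():
        missing = [spec.assay_names[i] for i in np.flatnonzero(np.isnan(vals))]
        raise ValueError(f"missing AUC value(s) for assay(s): {missing}")
    w = np.asarray(spec.weights, dtype=float)
    total = float(np.dot(w, vals))
    return total / w.sum() if spec.normalize_weights else total


def dichotomize(auc: float, threshold: float = 0.1) -> int:
    """Activity call: 1 iff AUC >= threshold (closed on the active side)."""
    return int(auc >= threshold)


def count_active_assays(assay_aucs: np.ndarray, floor: float = 0.0) -> int:
    """Number of component assays with AUC strictly above the floor."""
    vals = np.asarray(assay_aucs, dtype=float)
    return int((vals > floor).sum())


def label_confusion(full_call: int, subset_call: int) -> str:
    """Confusion label with the full-model call as truth."""
    try:
        return CONFUSION[(int(full_call), int(subset_call))]
    except KeyError:
        raise ValueError(f"calls must be 0/1, got ({full_call}, {subset_call})") from None


def score_chemicals(
    aucs: AssayAUCTable,
    spec: ModelSpec,
    reference: FullModelReference,
    chem_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Build the per-chemical prediction table.

    Scores every requested chemical present in both the AUC table and the
    full-model reference; chemicals missing any of the model's assay values
    are excluded and returned in the second element.  The returned frame is
    indexed by chem_id with columns: full_auc, full_call, subset_auc_med,
    subset_auc_lo, subset_auc_hi, subset_call, antagonist_flag,
    n_active_assays, confusion_label (plus full_lo/full_hi when the
    reference carries CI columns).
    """
    if chem_ids is None:
        chem_ids = [c for c in aucs.chem_ids if c in set(reference.chem_ids)]
    missing_assays = [a for a in spec.assay_names if a not in aucs.assay_names]
    if missing_assays:
        raise ValueError(f"AUC table lacks model assays: {missing_assays}")
    ref = reference.table
    unknown = [c for c in chem_ids if c not in ref.index or c not in aucs.auc_med.index]
    if unknown:
        raise ValueError(f"chemicals absent from AUC table or reference: {unknown[:5]}")

    med = aucs.auc_med.loc[chem_ids, spec.assay_names]
    lo = aucs.auc_lo.loc[chem_ids, spec.assay_names]
    hi = aucs.auc_hi.loc[chem_ids, spec.assay_names]

    complete = med.notna().all(axis=1) & lo.notna().all(axis=1) & hi.notna().all(axis=1)
    excluded = list(med.index[~complete])
    if excluded:
        logger.warning(
            "score_chemicals: %d chemical(s) excluded for missing model-assay values: %s%s",
            len(excluded), ", ".join(excluded[:5]), "..." if len(excluded) > 5 else "",
        )
    med, lo, hi = med[complete], lo[complete], hi[complete]

    w = np.asarray(spec.weights, dtype=float)
    denom = w.sum() if spec.normalize_weights else 1.0

    def _score(df: pd.DataFrame) -> np.ndarray:
        return df.to_numpy(dtype=float) @ w / denom

    out = pd.DataFrame(index=med.index.rename("chem_id"))
    out["full_auc"] = ref.loc[out.index, "full_auc"].astype(float)
    out["full_call"] = (out["full_auc"] >= spec.activity_threshold).astype(int)
    out["subset_auc_med"] = _score(med)
    out["subset_auc_lo"] = _score(lo)
    out["subset_auc_hi"] = _score(hi)
    out["subset_call"] = (out["subset_auc_med"] >= spec.activity_threshold).astype(int)
    out["antagonist_flag"] = ref.loc[out.index, "antagonist_flag"].astype(bool)
    out["n_active_assays"] = (
        med.to_numpy(dtype=float) > spec.assay_activity_floor
    ).sum(axis=1)
    out["confusion_label"] = [
        CONFUSION[(f, s)] for f, s in zip(out["full_call"], out["subset_call"])
    ]
    if reference.has_ci:
        out["full_lo"] = ref.loc[out.index, "full_lo"].astype(float)
        out["full_hi"] = ref.loc[out.index, "full_hi"].astype(float)
    return out, excluded
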