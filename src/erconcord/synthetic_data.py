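"""Synthetic fingerprint universes and assay AUC tables with ground truth.

Every pipeline stage is testable without external data: the universe
generator plants block structure in bit space (each cluster owns a random
feature mask; members switch mask bits on with high probability and
background bits with low probability), and the assay generator draws each
tested chemical from one of five activity archetypes that mirror the
behaviours the concordance analysis must separate:

* ``strong_agonist``   - high AUC across >=3 subset assays, clearly active
  in the full model (true positive, survives every triage filter);
* ``weak_agonist``     - modest AUC in 3 assays, full-model AUC just above
  threshold (true positive near the decision boundary);
* ``antagonist_like``  - high AUC only in the receptor-binding and
  dimerization assays that agonist and antagonist pathways share, inactive
  elsewhere, full-model agonist AUC below threshold and antagonist flag set
  (the subset model's structurally expected false positive);
* ``inactive``         - no activity anywhere;
* ``borderline``       - subset score straddling the 0.1 threshold with a
  CI that overlaps it, full model inactive (the noise-driven false
  positive that assay-count filtering should remove).

Noise is truncated-normal on the AUC scale (clip to [0, 1]) and is applied
only to assays with a non-zero archetype mean: an assay with no underlying
response reports exactly 0, so active-assay counts reflect the archetype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    AssayAUCTable,
    ChemicalRecord,
    ClusterAssignment,
    FingerprintMatrix,
    FullModelReference,
    ModelSpec,
)

__all__ = [
    "UniverseSpec",
    "ArchetypeSpec",
    "SyntheticUniverse",
    "gen_universe",
    "gen_tested_extras",
    "gen_assay_table",
    "default_model_spec",
    "expected_confusion",
    "ARCHETYPES",
    "SUBSET_ASSAYS",
]

SUBSET_ASSAYS = [
    "binding_cellfree",
    "dimerization_1440",
    "transactivation_trans",
    "proliferation_80hr",
]

ARCHETYPES = ["strong_agonist", "weak_agonist", "antagonist_like", "inactive", "borderline"]

# per-archetype mean AUC on the four subset assays, and the full-model base
ASSAY_MEANS: dict[str, tuple[float, float, float, float]] = {
    "strong_agonist": (0.55, 0.50, 0.60, 0.50),
    "weak_agonist": (0.0, 0.14, 0.22, 0.12),
    "antagonist_like": (0.55, 0.45, 0.0, 0.0),
    "inactive": (0.0, 0.0, 0.0, 0.0),
    "borderline": (0.0, 0.0, 0.22, 0.18),
}
FULL_AUC_BASE: dict[str, float] = {
    "strong_agonist": 0.50,
    "weak_agonist": 0.16,
    "antagonist_like": 0.03,
    "inactive": 0.0,
    "borderline": 0.05,
}
ANTAGONIST_ARCHETYPES = {"antagonist_like"}

DEFAULT_MIXTURE: dict[str, float] = {
    "strong_agonist": 0.10,
    "weak_agonist": 0.08,
    "antagonist_like": 0.04,
    "inactive": 0.62,
    "borderline": 0.16,
}


def default_model_spec() -> ModelSpec:
    """Equal-weight 4-assay model with the standard 0.1 activity threshold."""
    return ModelSpec(assay_names=list(SUBSET_ASSAYS), weights=[1.0, 1.0, 1.0, 1.0])


@dataclass
class UniverseSpec:
    """Planted-cluster fingerprint universe parameters."""

    n_clusters: int = 10
    cluster_sizes: int | list[int] = 20
    n_features: int = 729
    mask_size: int = 40
    within_profile_on_prob: float = 0.9
    background_on_prob: float = 0.02
    seed: int = 0

    def sizes(self) -> list[int]:
        if isinstance(self.cluster_sizes, int):
            return [self.cluster_sizes] * self.n_clusters
        if len(self.cluster_sizes) != self.n_clusters:
            raise ValueError("cluster_sizes length must equal n_clusters")
        return list(self.cluster_sizes)

    def __post_init__(self) -> None:
        for p in (self.within_profile_on_prob, self.background_on_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(s < 1 for s in self.sizes()):
            raise ValueError("cluster sizes must be >= 1")
        if self.mask_size > self.n_features:
            raise ValueError("mask_size cannot exceed n_features")


@dataclass
class SyntheticUniverse:
    records: list[ChemicalRecord]
    fingerprints: FingerprintMatrix
    truth: ClusterAssignment
    masks: list[np.ndarray]  # per-cluster on-bit index arrays
    spec: UniverseSpec


def _draw_member(rng: np.random.Generator, mask: np.ndarray, spec: UniverseSpec) -> np.ndarray:
    bits = (rng.random(spec.n_features) < spec.background_on_prob).astype(np.uint8)
    bits[mask] = (rng.random(len(mask)) < spec.within_profile_on_prob).astype(np.uint8)
    return bits


def gen_universe(spec: UniverseSpec) -> SyntheticUniverse:
    """Generate the clustered universe with ground-truth labels.

    Cluster masks are sampled without replacement across clusters whenever
    the feature space allows it, so distinct clusters occupy disjoint bit
    profiles and within/between similarity is well separated.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = spec.sizes()
    total_mask = spec.n_clusters * spec.mask_size
    if total_mask <= spec.n_features:
        pool = rng.permutation(spec.n_features)[:total_mask]
        masks = [
            np.sort(pool[i * spec.mask_size : (i + 1) * spec.mask_size])
            for i in range(spec.n_clusters)
        ]
    else:
        masks = [
            np.sort(rng.choice(spec.n_features, size=spec.mask_size, replace=False))
            for _ in range(spec.n_clusters)
        ]

    rows, chem_ids, labels = [], [], {}
    counter = 0
    for cluster_idx, (mask, size) in enumerate(zip(masks, sizes), start=1):
        for _ in range(size):
            counter += 1
            cid = f"SYN-{counter:06d}"
            chem_ids.append(cid)
            labels[cid] = cluster_idx
            rows.append(_draw_member(rng, mask, spec))

    fps = FingerprintMatrix(
        chem_ids,
        [f"bit_{j + 1:03d}" for j in range(spec.n_features)],
        np.vstack(rows),
    )
    records = [
        ChemicalRecord(chem_id=c, name=f"synthetic compound {i + 1}", in_universe=True)
        for i, c in enumerate(chem_ids)
    ]
    truth = ClusterAssignment(labels, cut_height=float("nan"), linkage_variant="planted")
    return SyntheticUniverse(records, fps, truth, masks, spec)


def gen_tested_extras(
    universe: SyntheticUniverse, n_extra: int, seed: int
) -> tuple[list[ChemicalRecord], FingerprintMatrix, ClusterAssignment]:
    """Extra tested chemicals outside the universe, drawn from cluster profiles.

    Each extra chemical is generated from a randomly chosen cluster's bit
    profile (its generating cluster is the ground-truth label), emulating
    assay-tested chemicals that are structural neighbours of the universe
    without being members of it.
    """
    rng = np.random.default_rng(seed)
    spec = universe.spec
    chem_ids, rows, labels = [], [], {}
    for i in range(n_extra):
        cluster_idx = int(rng.integers(spec.n_clusters)) + 1
        cid = f"SYN-T{i + 1:05d}"
        chem_ids.append(cid)
        labels[cid] = cluster_idx
        rows.append(_draw_member(rng, universe.masks[cluster_idx - 1], spec))
    fps = FingerprintMatrix(chem_ids, list(universe.fingerprints.feature_names), np.vstack(rows))
    records = [
        ChemicalRecord(chem_id=c, name=f"synthetic tested extra {i + 1}", in_tested_set=True)
        for i, c in enumerate(chem_ids)
    ]
    truth = ClusterAssignment.referencing(labels, universe.truth)
    return records, fps, truth


@dataclass
class ArchetypeSpec:
    """Archetype mixture and noise model for the assay AUC generator."""

    mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    assay_means: dict[str, tuple[float, ...]] = field(default_factory=lambda: dict(ASSAY_MEANS))
    full_auc_base: dict[str, float] = field(default_factory=lambda: dict(FULL_AUC_BASE))
    noise_sd: float = 0.05
    ci_halfwidth: float | None = None  # defaults to noise_sd
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.mixture) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        w = np.array([self.mixture.get(a, 0.0) for a in ARCHETYPES], dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("mixture weights must be non-negative and sum > 0")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def halfwidth(self) -> float:
        return self.noise_sd if self.ci_halfwidth is None else self.ci_halfwidth


def gen_assay_table(
    chem_ids: list[str], spec: ArchetypeSpec
) -> tuple[AssayAUCTable, FullModelReference, pd.Series]:
    """Draw per-chemical assay AUCs and full-model reference from archetypes.

    CI bounds are med -/+ the CI half-width (default: the noise sd), clipped
    to [0, 1]; an assay with a zero archetype mean reports exactly 0 with a
    degenerate CI.  Returns the AUC table, the full-model reference (AUC +
    antagonist flag), and the true archetype label per chemical.
    """
    rng = np.random.default_rng(spec.seed)
    probs = np.array([spec.mixture.get(a, 0.0) for a in ARCHETYPES], dtype=float)
    labels = rng.choice(ARCHETYPES, size=len(chem_ids), p=probs)

    n_assays = len(SUBSET_ASSAYS)
    med = np.zeros((len(chem_ids), n_assays))
    full_auc = np.zeros(len(chem_ids))
    antagonist = np.zeros(len(chem_ids), dtype=bool)
    for i, lab in enumerate(labels):
        means = np.asarray(spec.assay_means[lab], dtype=float)
        active = means > 0
        vals = means.copy()
        if spec.noise_sd > 0 and active.any():
            vals[active] = np.clip(
                means[active] + rng.normal(0.0, spec.noise_sd, active.sum()), 0.0, 1.0
            )
        med[i] = vals
        base = spec.full_auc_base[lab]
        if spec.noise_sd > 0 and base > 0:
            base = float(np.clip(base + rng.normal(0.0, spec.noise_sd), 0.0, 1.0))
        full_auc[i] = base
        antagonist[i] = lab in ANTAGONIST_ARCHETYPES

    hw = spec.halfwidth
    active_mask = med > 0
    lo = np.where(active_mask, np.clip(med - hw, 0.0, 1.0), 0.0)
    hi = np.where(active_mask, np.clip(med + hw, 0.0, 1.0), 0.0)

    idx = pd.Index(chem_ids, name="chem_id")
    table = AssayAUCTable(
        pd.DataFrame(med, index=idx, columns=SUBSET_ASSAYS),
        pd.DataFrame(lo, index=idx, columns=SUBSET_ASSAYS),
        pd.DataFrame(hi, index=idx, columns=SUBSET_ASSAYS),
    )
    reference = FullModelReference(
        pd.DataFrame({"full_auc": full_auc, "antagonist_flag": antagonist}, index=idx)
    )
    return table, reference, pd.Series(labels, index=idx, name="archetype")


def expected_confusion(labels: pd.Series, spec: ArchetypeSpec, threshold: float = 0.1) -> dict:
    """Zero-noise archetype -> confusion mapping, enumerated from the rules.

    Valid only for a noise-free generator: each archetype's calls follow
    deterministically from its mean profile, so global confusion counts are
    an exact function of the archetype counts.
    """
    mapping = {}
    for arch in ARCHETYPES:
        means = np.asarray(spec.assay_means[arch], dtype=float)
        subset_call = int(means.mean() >= threshold)
        full_call = int(spec.full_auc_base[arch] >= threshold)
        mapping[arch] = {(1, 1): "TP", (0, 0): "TN", (0, 1): "FP", (1, 0): "FN"}[
            (full_call, subset_call)
        ]
    counts = labels.value_counts()
    out = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for arch, n in counts.items():
        out[mapping[arch]] += int(n)
    return out
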