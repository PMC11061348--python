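"""Configuration-driven end-to-end driver.

``make_synthetic`` writes the five pipeline input files (plus ground truth)
from the synthetic generators; ``run_pipeline`` executes
load -> cluster -> knn -> score -> concordance -> triage -> prioritization
and writes the seven output tables plus a run log.  All randomness derives
from the config's required ``seed``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cluster_size_profile, pairwise_distances, ward_cut
from .concordance import cluster_confusion, global_discrepancy_table, partition_by_prevalence
from .data_model import (
    ChemicalRecord,
    ModelSpec,
    join_datasets,
    load_assay_aucs,
    load_chemicals,
    load_fingerprints,
    load_full_model,
    load_model_spec,
    write_chemicals,
)
from .knn_map import coverage_report, knn_assign, select_k
from .synthetic_data import (
    ArchetypeSpec,
    UniverseSpec,
    default_model_spec,
    gen_assay_table,
    gen_tested_extras,
    gen_universe,
)
from .triage import TriageConfig, prioritization_list, triage_false_positives

logger = logging.getLogger("erconcord")

__all__ = ["load_config", "make_synthetic", "run_pipeline", "report_text", "PipelineResult"]

DEFAULT_CONFIG: dict[str, Any] = {
    "linkage_variant": "ward_d2",
    "cut_height": 2.0,
    "k_candidates": [1, 2, 3, 4, 5],
    "split_fraction": 0.8,
    "activity_threshold": 0.1,
    "tp_quantile": 0.25,
    "min_active_assays": 3,
    "min_cluster_n": 2,
    "normalize_weights": True,
    # synthetic-input generation
    "universe": {},
    "archetypes": {},
    "tested_fraction": 0.5,
    "n_tested_extra": 60,
}


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> dict:
    """Merge a YAML config over the defaults; ``seed`` is mandatory."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, Mapping):
            raise ValueError(f"{path}: config must be a YAML mapping")
        cfg.update(user)
    if overrides:
        cfg.update(overrides)
    if "seed" not in cfg or cfg["seed"] is None:
        raise ValueError("config must provide an explicit integer 'seed'")
    cfg["seed"] = int(cfg["seed"])
    return cfg


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive independent child seeds (< 2**31) from the master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def make_synthetic(config: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Write synthetic pipeline inputs with known ground truth.

    The tested set is a random half (``tested_fraction``) of the universe
    plus ``n_tested_extra`` structurally similar chemicals outside it, so
    the KNN mapping stage has both self-consistency cases and genuine
    queries.  Outputs: chemicals.csv, fingerprints.csv, assay_aucs.csv,
    model_spec.yaml, full_model.csv, ground_truth.csv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_universe, seed_extras, seed_tested, seed_assays = _spawn_seeds(config["seed"], 4)

    uspec = UniverseSpec(**{**config.get("universe", {}), "seed": seed_universe})
    universe = gen_universe(uspec)
    extras, extra_fps, extra_truth = gen_tested_extras(
        universe, int(config.get("n_tested_extra", 60)), seed_extras
    )

    rng = np.random.default_rng(seed_tested)
    n_univ = len(universe.records)
    n_tested_univ = int(round(float(config.get("tested_fraction", 0.5)) * n_univ))
    tested_univ_idx = set(rng.choice(n_univ, size=n_tested_univ, replace=False).tolist())
    records: list[ChemicalRecord] = []
    for i, rec in enumerate(universe.records):
        rec.in_tested_set = i in tested_univ_idx
        records.append(rec)
    records.extend(extras)
    tested_ids = [r.chem_id for r in records if r.in_tested_set]

    aspec = ArchetypeSpec(**{**config.get("archetypes", {}), "seed": seed_assays})
    aucs, reference, archetypes = gen_assay_table(tested_ids, aspec)

    fps = universe.fingerprints
    all_fps = pd.concat([fps.to_frame(), extra_fps.to_frame()], ignore_index=True)

    write_chemicals(records, out / "chemicals.csv")
    all_fps.to_csv(out / "fingerprints.csv", index=False)
    aucs.write_csv(out / "assay_aucs.csv")
    default_model_spec().to_yaml(out / "model_spec.yaml")
    reference.write_csv(out / "full_model.csv")

    truth_labels = {**universe.truth.labels, **extra_truth.labels}
    truth = pd.DataFrame(
        {"chem_id": list(truth_labels), "true_cluster": list(truth_labels.values())}
    )
    truth["archetype"] = truth["chem_id"].map(archetypes).fillna("")
    truth.to_csv(out / "ground_truth.csv", index=False)
    logger.info(
        "make_synthetic: universe=%d tested=%d (extras=%d) -> %s",
        n_univ, len(tested_ids), len(extras), out,
    )
    return out


class PipelineResult:
    """In-memory results of a full pipeline run (also written to disk)."""

    def __init__(self, **kw: Any) -> None:
        self.__dict__.update(kw)


def run_pipeline(
    config: Mapping[str, Any], input_dir: str | Path, out_dir: str | Path
) -> PipelineResult:
    """Execute the full analysis and write its seven output tables."""
    inp, out = Path(input_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "seed" not in config:
        raise ValueError("config must provide an explicit integer 'seed'")

    # --- load -------------------------------------------------------------
    chems = load_chemicals(inp / "chemicals.csv")
    fps = load_fingerprints(inp / "fingerprints.csv")
    aucs = load_assay_aucs(inp / "assay_aucs.csv")
    spec = load_model_spec(inp / "model_spec.yaml")
    spec.activity_threshold = float(config["activity_threshold"])
    spec.normalize_weights = bool(config["normalize_weights"])
    reference = load_full_model(inp / "full_model.csv")
    bundle = join_datasets(chems, fps, aucs, reference)

    # --- cluster the universe --------------------------------------------
    univ_fps = fps.subset(bundle.universe_ids)
    dist = pairwise_distances(univ_fps)
    assign = ward_cut(dist, float(config["cut_height"]), str(config["linkage_variant"]))
    profile = cluster_size_profile(assign)

    # --- k selection and mapping of the tested set ------------------------
    ksel = select_k(
        univ_fps,
        assign,
        k_candidates=tuple(config["k_candidates"]),
        split_fraction=float(config["split_fraction"]),
        seed=config["seed"],
    )
    tested_fps = fps.subset(bundle.tested_ids)
    tested_assign = knn_assign(univ_fps, assign, tested_fps, ksel.chosen_k)
    overlap = bundle.overlap_ids
    self_consistent = sum(
        1 for c in overlap if tested_assign.labels[c] == assign.labels[c]
    )
    coverage = coverage_report(assign, tested_assign)

    # --- score and compare -------------------------------------------------
    preds, excluded = er_score(aucs, spec, reference, bundle.tested_ids)
    stats, below_floor = cluster_confusion(preds, tested_assign, int(config["min_cluster_n"]))
    stats_all, _ = cluster_confusion(preds, tested_assign, min_cluster_n=1)
    partition = partition_by_prevalence(stats).assign(scope="min_cluster_n")
    partition_all = partition_by_prevalence(stats_all).assign(scope="all_clusters")
    partition_both = pd.concat([partition, partition_all], ignore_index=True)
    discrepancy = global_discrepancy_table(preds)

    # --- triage and prioritization -----------------------------------------
    tcfg = TriageConfig(
        tp_quantile=float(config["tp_quantile"]),
        min_active_assays=int(config["min_active_assays"]),
        activity_threshold=float(config["activity_threshold"]),
    )
    triage = triage_false_positives(preds, tcfg)
    ranked, enrichment, rescued = prioritization_list(preds, tested_assign, tcfg)

    # --- write -------------------------------------------------------------
    assign.to_frame().to_csv(out / "clusters.csv", index=False)
    pd.DataFrame(
        {"k": list(ksel.accuracy_by_k), "accuracy": list(ksel.accuracy_by_k.values())}
    ).assign(chosen_k=ksel.chosen_k).to_csv(out / "kselect.csv", index=False)
    preds.rename_axis("chem_id").reset_index().assign(
        cluster_id=lambda df: df["chem_id"].map(tested_assign.labels)
    ).to_csv(out / "predictions.csv", index=False)
    stats.to_csv(out / "cluster_stats.csv", index=False)
    partition_both.to_csv(out / "partition.csv", index=False)
    triage.per_chemical.rename_axis("chem_id").reset_index().to_csv(out / "triage.csv", index=False)
    ranked.to_csv(out / "priority.csv", index=False)

    log_lines = {
        "software_version": __version__,
        "seed": config["seed"],
        "parameters": {
            k: config[k]
            for k in (
                "linkage_variant", "cut_height", "k_candidates", "split_fraction",
                "activity_threshold", "tp_quantile", "min_active_assays",
                "min_cluster_n", "normalize_weights",
            )
        },
        "counts": {
            "n_universe": len(bundle.universe_ids),
            "n_tested": len(bundle.tested_ids),
            "n_overlap": len(overlap),
            "n_missing_fingerprint": len(bundle.missing_fingerprint_ids),
            "n_excluded_incomplete_assays": len(excluded),
            "n_clusters": assign.n_clusters,
            "n_singleton_clusters": profile.n_singletons,
            "n_doubleton_clusters": profile.n_doubletons,
            "n_clusters_with_tested": coverage["n_clusters_with_tested"],
            "knn_self_consistent": self_consistent,
            "chosen_k": ksel.chosen_k,
            "global_confusion": {k: discrepancy[k] for k in ("tp", "fp", "tn", "fn")},
            "triage_categories": triage.counts,
            "tp_auc_quantile": triage.tp_quantile_value,
        },
    }
    (out / "run_log.txt").write_text(json.dumps(log_lines, indent=2, default=str) + "\n")

    return PipelineResult(
        bundle=bundle,
        assignment=assign,
        size_profile=profile,
        kselection=ksel,
        tested_assignment=tested_assign,
        self_consistent=self_consistent,
        n_overlap=len(overlap),
        coverage=coverage,
        predictions=preds,
        excluded=excluded,
        cluster_stats=stats,
        cluster_stats_all=stats_all,
        below_floor=below_floor,
        partition=partition_both,
        discrepancy=discrepancy,
        triage=triage,
        ranked=ranked,
        enrichment=enrichment,
        rescued=rescued,
        out_dir=out,
    )


def er_score(aucs, spec: ModelSpec, reference, tested_ids):
    """Score the tested chemicals with the subset model (thin wrapper)."""
    from .er_models import score_chemicals

    scorable = [c for c in tested_ids if c in set(reference.chem_ids)]
    dropped = [c for c in tested_ids if c not in set(reference.chem_ids)]
    if dropped:
        logger.warning("%d tested chemical(s) missing from the full-model reference", len(dropped))
    preds, excluded = score_chemicals(aucs, spec, reference, scorable)
    return preds, excluded + dropped


def report_text(results_dir: str | Path) -> str:
    """Plain-text summary: cluster partition breakdown and triage categories."""
    res = Path(results_dir)
    partition = pd.read_csv(res / "partition.csv")
    triage = pd.read_csv(res / "triage.csv")
    stats = pd.read_csv(res / "cluster_stats.csv")
    log = json.loads((res / "run_log.txt").read_text())

    lines = ["Cluster partition by full-model prevalence", "=" * 44]
    lines.append(partition.to_string(index=False))
    lines.append("")
    lines.append("False-positive triage categories")
    lines.append("=" * 32)
    if len(triage):
        counts = triage["category"].value_counts()
        for cat, n in counts.items():
            lines.append(f"{cat:>24}: {n}")
    else:
        lines.append("no false positives")
    mixed = stats[(stats["prevalence"] > 0) & (stats["prevalence"] < 1)]
    ba = mixed["balanced_accuracy"].dropna()
    acc = mixed["accuracy"].dropna()
    lines.append("")
    lines.append("Mixed-prevalence cluster performance")
    lines.append("=" * 36)
    if len(ba):
        lines.append(f"balanced accuracy range: {ba.min():.3f} - {ba.max():.3f} (mean {ba.mean():.3f})")
    if len(acc):
        lines.append(f"accuracy range:          {acc.min():.3f} - {acc.max():.3f} (mean {acc.mean():.3f})")
    lines.append("")
    lines.append(f"seed={log['seed']}  version={log['software_version']}")
    return "\n".join(lines) + "\n"
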