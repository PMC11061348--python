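"""k-nearest-neighbour mapping of tested chemicals into universe clusters.

The universe partition provides "known" cluster labels; chemicals outside
the universe are assigned by majority vote of their k nearest universe
chemicals under Tanimoto distance.  k is chosen by an 80/20 split of the
labelled universe, scoring each candidate k by hold-out accuracy.

Tie rules (deterministic by construction):

* neighbour distance ties are broken by lexicographically lowest training
  chem_id;
* majority-vote ties are broken by the cluster of the single nearest
  neighbour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import ClusterAssignment, FingerprintMatrix

logger = logging.getLogger("erconcord")

__all__ = ["KSelectionResult", "select_k", "knn_assign", "coverage_report"]


@dataclass
class KSelectionResult:
    k_candidates: list[int]
    accuracy_by_k: dict[int, float]
    chosen_k: int
    split_fraction: float = 0.8
    seed: int = 0
    skipped_k: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.accuracy_by_k:
            best = max(self.accuracy_by_k.values())
            if self.accuracy_by_k[self.chosen_k] != best:
                raise ValueError("chosen_k must maximize accuracy_by_k")


def _neighbour_order(dists: np.ndarray, train_ids: np.ndarray) -> np.ndarray:
    """Sort training indices by (distance, chem_id): lexsort's last key is primary."""
    return np.lexsort((train_ids, dists))


def _vote(order: np.ndarray, train_labels: np.ndarray, k: int) -> int:
    top = train_labels[order[:k]]
    clusters, counts = np.unique(top, return_counts=True)
    winners = clusters[counts == counts.max()]
    if len(winners) == 1:
        return int(winners[0])
    return int(train_labels[order[0]])


def knn_assign(
    train_fps: FingerprintMatrix,
    train_assign: ClusterAssignment,
    query_fps: FingerprintMatrix,
    k: int,
) -> ClusterAssignment:
    """Assign each query chemical the majority cluster of its k nearest
    training chemicals (Tanimoto distance, deterministic tie rules)."""
    if train_fps.n_chemicals == 0:
        raise ValueError("empty training set")
    if k < 1:
        raise ValueError("k must be >= 1")
    missing = [c for c in train_fps.chem_ids if c not in train_assign.labels]
    if missing:
        raise ValueError(f"training chemicals without cluster labels: {missing[:5]}")
    k_eff = min(k, train_fps.n_chemicals)
    if k_eff < k:
        logger.warning("knn_assign: k=%d capped to training size %d", k, k_eff)

    train_ids = np.asarray(train_fps.chem_ids)
    train_labels = np.asarray([train_assign.labels[c] for c in train_fps.chem_ids])
    d = cdist(query_fps.bits.astype(bool), train_fps.bits.astype(bool), metric="jaccard")

    labels: dict[str, int] = {}
    for i, chem_id in enumerate(query_fps.chem_ids):
        order = _neighbour_order(d[i], train_ids)
        labels[chem_id] = _vote(order, train_labels, k_eff)
    return ClusterAssignment.referencing(labels, train_assign)


def select_k(
    fps: FingerprintMatrix,
    assign: ClusterAssignment,
    k_candidates: tuple[int, ...] = (1, 2, 3, 4, 5),
    split_fraction: float = 0.8,
    seed: int | None = None,
) -> KSelectionResult:
    """Choose k by hold-out accuracy on a random split of the labelled universe.

    The universe is split uniformly at random (``split_fraction`` into
    training); each candidate k predicts the held-out chemicals' cluster
    labels and is scored by the fraction that match.  Ties go to the
    smallest k.  Candidates exceeding the training size are skipped with a
    warning.
    """
    if seed is None:
        raise ValueError("select_k requires an explicit seed")
    missing = [c for c in fps.chem_ids if c not in assign.labels]
    if missing:
        raise ValueError(f"chemicals without cluster labels: {missing[:5]}")
    rng = np.random.default_rng(seed)
    n = fps.n_chemicals
    perm = rng.permutation(n)
    n_train = int(round(split_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError("split leaves an empty training or test set")
    train_idx, test_idx = perm[:n_train], perm[n_train:]

    train_ids = np.asarray(fps.chem_ids)[train_idx]
    test_ids = np.asarray(fps.chem_ids)[test_idx]
    train_labels = np.asarray([assign.labels[c] for c in train_ids])
    true_test = np.asarray([assign.labels[c] for c in test_ids])
    d = cdist(fps.bits[test_idx].astype(bool), fps.bits[train_idx].astype(bool), metric="jaccard")
    orders = [_neighbour_order(d[i], train_ids) for i in range(len(test_idx))]

    accuracy_by_k: dict[int, float] = {}
    skipped: list[int] = []
    for k in k_candidates:
        if k > n_train:
            logger.warning("select_k: skipping k=%d > training size %d", k, n_train)
            skipped.append(k)
            continue
        pred = np.array([_vote(orders[i], train_labels, k) for i in range(len(test_idx))])
        accuracy_by_k[k] = float((pred == true_test).mean())
    if not accuracy_by_k:
        raise ValueError("no usable k candidates")
    best = max(accuracy_by_k.values())
    chosen_k = min(k for k, acc in accuracy_by_k.items() if acc == best)
    logger.info("select_k: accuracies %s -> k=%d", accuracy_by_k, chosen_k)
    return KSelectionResult(
        k_candidates=list(k_candidates),
        accuracy_by_k=accuracy_by_k,
        chosen_k=chosen_k,
        split_fraction=split_fraction,
        seed=seed,
        skipped_k=skipped,
    )


def coverage_report(universe_assign: ClusterAssignment, tested_assign: ClusterAssignment) -> dict:
    """How much of the universe cluster space the tested set reaches."""
    n_universe = universe_assign.n_clusters
    receiving = sorted(set(tested_assign.labels.values()))
    report = {
        "n_universe_clusters": n_universe,
        "n_clusters_with_tested": len(receiving),
        "coverage_fraction": len(receiving) / n_universe if n_universe else float("nan"),
    }
    logger.info(
        "coverage: %d of %d universe clusters contain >=1 tested chemical",
        report["n_clusters_with_tested"], n_universe,
    )
    return report
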