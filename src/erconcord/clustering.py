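"""Tanimoto distances and Ward hierarchical clustering with a height cut.

The universe of chemicals is clustered on binary substructure fingerprints:
pairwise Tanimoto distance (1 - Tanimoto coefficient, identical to the
Jaccard distance on bit vectors), agglomerated with Ward's method, and the
tree cut at an absolute height.

Two Ward dialects exist in common statistical software and give different
merge heights (and therefore different partitions at a fixed cut height):

* ``ward_d2`` - Ward's minimum-variance objective applied to squared
  dissimilarities, heights reported on the original distance scale.  This is
  scipy's ``linkage(method="ward")`` and R's ``hclust(method="ward.D2")``.
* ``ward_d`` - the Lance-Williams Ward update applied to the raw
  dissimilarities (R's historical ``hclust(method="ward.D")``).

Cluster counts at a fixed cut height are dialect-sensitive, so the dialect
is an explicit parameter and is recorded on the resulting assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .data_model import ClusterAssignment, DistanceMatrix, FingerprintMatrix, relabel_first_appearance

logger = logging.getLogger("erconcord")

LINKAGE_VARIANTS = ("ward_d", "ward_d2")

__all__ = [
    "tanimoto_distance",
    "pairwise_distances",
    "ward_linkage",
    "ward_cut",
    "cluster_size_profile",
    "ClusterSizeProfile",
]


def tanimoto_distance(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto distance 1 - c/(a + b - c) between two binary fingerprints.

    ``c`` is the number of shared on-bits, ``a`` and ``b`` the on-bit counts
    of each vector.  Two all-zero fingerprints are at distance 0 (with a
    degenerate-fingerprint warning); one all-zero vector against a non-zero
    one is at distance 1.
    """
    a_vec = np.asarray(fp_a).astype(bool)
    b_vec = np.asarray(fp_b).astype(bool)
    if a_vec.shape != b_vec.shape:
        raise ValueError(f"fingerprint length mismatch: {a_vec.shape} vs {b_vec.shape}")
    a = int(a_vec.sum())
    b = int(b_vec.sum())
    if a == 0 and b == 0:
        logger.warning("tanimoto_distance: both fingerprints are all-zero; returning 0")
        return 0.0
    c = int((a_vec & b_vec).sum())
    return 1.0 - c / (a + b - c)


def pairwise_distances(fps: FingerprintMatrix) -> DistanceMatrix:
    """All-pairs Tanimoto distance matrix over a fingerprint matrix."""
    if fps.n_chemicals < 2:
        raise ValueError("pairwise distances need at least 2 chemicals")
    bits = fps.bits.astype(bool)
    zero_rows = ~bits.any(axis=1)
    if zero_rows.any():
        degenerate = [fps.chem_ids[i] for i in np.flatnonzero(zero_rows)]
        logger.warning(
            "pairwise_distances: %d all-zero fingerprint(s): %s",
            len(degenerate), ", ".join(degenerate),
        )
    # Jaccard distance on boolean vectors == Tanimoto distance; scipy defines
    # d = 0 for two all-zero vectors, matching the degenerate rule above.
    cond = pdist(bits, metric="jaccard")
    return DistanceMatrix(list(fps.chem_ids), squareform(cond))


def ward_linkage(dist: DistanceMatrix, linkage_variant: str = "ward_d2") -> np.ndarray:
    """Build the Ward merge tree for a distance matrix in the given dialect.

    ward_d heights are recovered from scipy's ward_d2 through the exact
    identity  ward_d(d) = ward_d2(sqrt(d))**2  (same merge order, heights on
    the raw-dissimilarity scale).
    """
    if linkage_variant not in LINKAGE_VARIANTS:
        raise ValueError(f"unknown linkage variant {linkage_variant!r}; use one of {LINKAGE_VARIANTS}")
    if not np.isfinite(dist.d).all():
        raise ValueError("distance matrix contains non-finite entries")
    cond = squareform(dist.d, checks=False)
    if linkage_variant == "ward_d2":
        return linkage(cond, method="ward")
    z = linkage(np.sqrt(cond), method="ward")
    z = z.copy()
    z[:, 2] = z[:, 2] ** 2
    return z


def ward_cut(
    dist: DistanceMatrix,
    cut_height: float,
    linkage_variant: str = "ward_d2",
) -> ClusterAssignment:
    """Cut the Ward tree at an absolute height and relabel clusters 1..K.

    Chemicals whose cophenetic merge height is <= ``cut_height`` share a
    cluster.  Ids are assigned in order of first member appearance in the
    input chemical order.
    """
    if cut_height <= 0:
        raise ValueError("cut_height must be positive")
    z = ward_linkage(dist, linkage_variant)
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = relabel_first_appearance(dist.chem_ids, raw)
    assign = ClusterAssignment(labels, cut_height=cut_height, linkage_variant=linkage_variant)
    logger.info(
        "ward_cut: %d chemicals -> %d clusters (cut=%g, %s)",
        len(dist.chem_ids), assign.n_clusters, cut_height, linkage_variant,
    )
    return assign


@dataclass
class ClusterSizeProfile:
    """Cluster size table plus singleton/doubleton counts used to judge cuts."""

    sizes: pd.Series  # cluster_id -> member count
    n_singletons: int
    n_doubletons: int

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def n_chemicals(self) -> int:
        return int(self.sizes.sum())


def cluster_size_profile(assign: ClusterAssignment) -> ClusterSizeProfile:
    """Summarize cluster sizes; small-cluster counts guide cut-height choice."""
    if not assign.labels:
        raise ValueError("empty cluster assignment")
    sizes = assign.as_series().value_counts().sort_index()
    sizes.index.name = "cluster_id"
    sizes.name = "size"
    return ClusterSizeProfile(
        sizes=sizes,
        n_singletons=int((sizes == 1).sum()),
        n_doubletons=int((sizes == 2).sum()),
    )
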