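"""Typed containers and CSV/YAML ingestion for the concordance pipeline.

All interchange is delimited text: a chemical record table, a wide binary
fingerprint matrix, a long-format chemical x assay AUC table, a YAML model
specification, and a full-model reference prediction table.  Loaders
validate invariants up front so downstream stages can assume clean inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("erconcord")

__all__ = [
    "ChemicalRecord",
    "FingerprintMatrix",
    "DistanceMatrix",
    "ClusterAssignment",
    "AssayAUCTable",
    "ModelSpec",
    "FullModelReference",
    "DataBundle",
    "load_chemicals",
    "load_fingerprints",
    "load_assay_aucs",
    "load_model_spec",
    "load_full_model",
    "write_chemicals",
    "join_datasets",
]


@dataclass
class ChemicalRecord:
    """One substance: identifiers, names, structure strings, set membership."""

    chem_id: str
    casrn: str = ""
    name: str = ""
    smiles: str = ""
    qsar_smiles: str = ""
    in_universe: bool = False
    in_tested_set: bool = False

    def __post_init__(self) -> None:
        if not self.chem_id:
            raise ValueError("chem_id must be a non-empty string")


@dataclass
class FingerprintMatrix:
    """Binary chemical x substructure-feature matrix keyed by chemical id.

    ``bits`` is an (n_chemicals, n_features) array of {0, 1}; row order
    follows ``chem_ids``.
    """

    chem_ids: list[str]
    feature_names: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2:
            raise ValueError("bits must be a 2-D matrix")
        n, m = self.bits.shape
        if n != len(self.chem_ids):
            raise ValueError(f"{n} rows but {len(self.chem_ids)} chem_ids")
        if m != len(self.feature_names):
            raise ValueError(f"{m} columns but {len(self.feature_names)} feature names")
        if len(set(self.chem_ids)) != len(self.chem_ids):
            raise ValueError("chem_ids must be unique")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint entries must all be 0 or 1")
        self.bits = self.bits.astype(np.uint8)

    @property
    def n_chemicals(self) -> int:
        return len(self.chem_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def index_of(self, chem_id: str) -> int:
        try:
            return self.chem_ids.index(chem_id)
        except ValueError:
            raise KeyError(chem_id) from None

    def subset(self, chem_ids: Sequence[str]) -> "FingerprintMatrix":
        idx = [self.index_of(c) for c in chem_ids]
        return FingerprintMatrix(list(chem_ids), list(self.feature_names), self.bits[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.bits, columns=self.feature_names)
        df.insert(0, "chem_id", self.chem_ids)
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class DistanceMatrix:
    """Square symmetric pairwise distance matrix with zero diagonal in [0, 1]."""

    chem_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.chem_ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.isfinite(self.d).all():
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if self.d.min() < -1e-12 or self.d.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")


@dataclass
class ClusterAssignment:
    """chem_id -> positive integer cluster id, with the cut that produced it.

    Cluster ids are relabelled to a contiguous 1..K range in order of first
    appearance in the input chemical order, so labels are deterministic for a
    fixed ordering while the partition itself is order-invariant.
    """

    labels: dict[str, int]
    cut_height: float = float("nan")
    linkage_variant: str = ""

    def __post_init__(self) -> None:
        if self.labels:
            ids = set(self.labels.values())
            if min(ids) < 1:
                raise ValueError("cluster ids must be positive integers")
            if ids != set(range(1, len(ids) + 1)):
                raise ValueError("cluster ids must form a contiguous 1..K range")

    @classmethod
    def referencing(
        cls, labels: dict[str, int], parent: "ClusterAssignment"
    ) -> "ClusterAssignment":
        """Build an assignment whose ids reference an existing partition.

        Used for mapped (e.g. KNN-assigned) chemicals: their labels point
        into the parent universe partition and need not cover a contiguous
        1..K range themselves, so the contiguity invariant is checked against
        the parent instead.
        """
        valid = set(parent.labels.values())
        stray = {lab for lab in labels.values() if lab not in valid}
        if stray:
            raise ValueError(f"labels reference unknown parent clusters: {sorted(stray)[:5]}")
        obj = cls.__new__(cls)
        obj.labels = dict(labels)
        obj.cut_height = parent.cut_height
        obj.linkage_variant = parent.linkage_variant
        return obj

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="cluster_id")

    def to_frame(self) -> pd.DataFrame:
        return (
            self.as_series()
            .rename_axis("chem_id")
            .reset_index()
            .assign(cut_height=self.cut_height, linkage_variant=self.linkage_variant)
        )


def relabel_first_appearance(
    chem_ids: Sequence[str], raw_labels: Sequence[int]
) -> dict[str, int]:
    """Relabel arbitrary integer labels to 1..K by first appearance order."""
    mapping: dict[int, int] = {}
    out: dict[str, int] = {}
    for cid, lab in zip(chem_ids, raw_labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[cid] = mapping[lab]
    return out


@dataclass
class AssayAUCTable:
    """Chemical x assay AUC scores: median and 95% CI bounds, all in [0, 1].

    Stored as three aligned DataFrames indexed by chem_id with assay columns.
    Missing values (NaN) are permitted; scoring excludes chemicals missing
    any of a model's assays.
    """

    auc_med: pd.DataFrame
    auc_lo: pd.DataFrame
    auc_hi: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("auc_lo", "auc_hi"):
            other = getattr(self, name)
            if not other.index.equals(self.auc_med.index) or not other.columns.equals(
                self.auc_med.columns
            ):
                raise ValueError(f"{name} is not aligned with auc_med")
        for name in ("auc_med", "auc_lo", "auc_hi"):
            vals = getattr(self, name).to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError(f"{name} values must lie in [0, 1]")
        lo = self.auc_lo.to_numpy(dtype=float)
        med = self.auc_med.to_numpy(dtype=float)
        hi = self.auc_hi.to_numpy(dtype=float)
        ok = np.isfinite(lo) & np.isfinite(med) & np.isfinite(hi)
        if ((lo[ok] > med[ok] + 1e-12) | (med[ok] > hi[ok] + 1e-12)).any():
            raise ValueError("CI ordering violated: need auc_lo <= auc_med <= auc_hi")

    @property
    def chem_ids(self) -> list[str]:
        return list(self.auc_med.index)

    @property
    def assay_names(self) -> list[str]:
        return list(self.auc_med.columns)

    def n_missing(self) -> int:
        return int(self.auc_med.isna().sum().sum())

    def to_long(self) -> pd.DataFrame:
        frames = []
        for name, df in (("auc_med", self.auc_med), ("auc_lo", self.auc_lo), ("auc_hi", self.auc_hi)):
            frames.append(
                df.rename_axis("chem_id")
                .reset_index()
                .melt(id_vars="chem_id", var_name="assay", value_name=name)
                .set_index(["chem_id", "assay"])
            )
        return pd.concat(frames, axis=1).reset_index()

    def write_csv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False)


@dataclass
class ModelSpec:
    """A reduced (subset) agonist model: assays, weights, call threshold.

    ``activity_threshold`` dichotomizes the model AUC (call active iff
    AUC >= threshold); ``assay_activity_floor`` is the strict-greater floor
    used when counting active component assays.
    """

    assay_names: list[str]
    weights: list[float]
    activity_threshold: float = 0.1
    assay_activity_floor: float = 0.0
    normalize_weights: bool = True

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.assay_names):
            raise ValueError("weights and assay_names must have equal length")
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if not (w > 0).any():
            raise ValueError("at least one weight must be positive")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "assays": list(self.assay_names),
            "weights": [float(w) for w in self.weights],
            "activity_threshold": float(self.activity_threshold),
            "assay_activity_floor": float(self.assay_activity_floor),
            "normalize_weights": bool(self.normalize_weights),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass
class FullModelReference:
    """Reference predictions from the full agonist model, used as truth.

    ``table`` is indexed by chem_id with columns ``full_auc`` (in [0, 1]) and
    ``antagonist_flag`` (bool, the pathway model's "max receptor" antagonist
    designation).  Optional ``full_lo``/``full_hi`` CI columns are carried
    through when present.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"full_auc", "antagonist_flag"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"full-model reference missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValueError("full-model reference has duplicate chem_ids")
        auc = self.table["full_auc"].to_numpy(dtype=float)
        if np.isnan(auc).any() or auc.min() < 0 or auc.max() > 1:
            raise ValueError("full_auc must lie in [0, 1] with no missing values")
        self.table = self.table.copy()
        self.table["antagonist_flag"] = self.table["antagonist_flag"].astype(bool)

    @property
    def chem_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def has_ci(self) -> bool:
        return {"full_lo", "full_hi"} <= set(self.table.columns)

    def write_csv(self, path: str | Path) -> None:
        self.table.rename_axis("chem_id").reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# loaders


def _read_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"chem_id": str})
    if df.empty:
        raise ValueError(f"{path}: file contains no data rows")
    return df


_BOOLISH = {
    "true": True, "1": True, "yes": True, "t": True,
    "false": False, "0": False, "no": False, "f": False, "": False,
}


def _coerce_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float, np.integer, np.floating)):
        if pd.isna(value):
            return False
        return bool(value)
    key = str(value).strip().lower()
    if key in _BOOLISH:
        return _BOOLISH[key]
    raise ValueError(f"cannot interpret {value!r} as boolean")


def load_chemicals(path: str | Path) -> list[ChemicalRecord]:
    """Read the chemical record table.

    Only ``chem_id`` is required; other columns are optional and default to
    empty/false.  Duplicate chem_ids collapse to the first occurrence with a
    warning.  Unknown columns are ignored.
    """
    df = _read_csv(path)
    if "chem_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'chem_id'")
    dup_mask = df["chem_id"].duplicated()
    n_dups = int(dup_mask.sum())
    if n_dups:
        dup_ids = sorted(df.loc[dup_mask, "chem_id"].unique())
        logger.warning(
            "%s: %d duplicate chem_id rows collapsed to first occurrence (%s%s)",
            path, n_dups, ", ".join(dup_ids[:5]), "..." if len(dup_ids) > 5 else "",
        )
        df = df[~dup_mask]

    def _str(row: pd.Series, col: str) -> str:
        val = row.get(col, "")
        return "" if pd.isna(val) else str(val)

    records = []
    for _, row in df.iterrows():
        records.append(
            ChemicalRecord(
                chem_id=str(row["chem_id"]),
                casrn=_str(row, "casrn"),
                name=_str(row, "name"),
                smiles=_str(row, "smiles"),
                qsar_smiles=_str(row, "qsar_smiles"),
                in_universe=_coerce_bool(row.get("in_universe", False)),
                in_tested_set=_coerce_bool(row.get("in_tested_set", False)),
            )
        )
    return records


def write_chemicals(records: Iterable[ChemicalRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chem_id": r.chem_id,
                "casrn": r.casrn,
                "name": r.name,
                "smiles": r.smiles,
                "qsar_smiles": r.qsar_smiles,
                "in_universe": r.in_universe,
                "in_tested_set": r.in_tested_set,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def load_fingerprints(path: str | Path) -> FingerprintMatrix:
    """Read a wide fingerprint table: chem_id column plus one column per bit.

    Every value must be exactly 0 or 1 (after an exact-integer check); any
    other value is a hard error naming the offending row and column.
    """
    df = _read_csv(path)
    if "chem_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'chem_id'")
    chem_ids = df["chem_id"].astype(str).tolist()
    feature_cols = [c for c in df.columns if c != "chem_id"]
    raw = df[feature_cols].to_numpy()
    numeric = df[feature_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(numeric) | (numeric != np.floor(numeric)) | ~np.isin(numeric, (0.0, 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: fingerprint value {raw[i, j]!r} at chem_id={chem_ids[i]}, "
            f"column={feature_cols[j]} is not 0 or 1"
        )
    return FingerprintMatrix(chem_ids, feature_cols, numeric.astype(np.uint8))


def load_assay_aucs(path: str | Path) -> AssayAUCTable:
    """Read a long-format AUC table: chem_id, assay, auc_med, auc_lo, auc_hi."""
    df = _read_csv(path)
    required = {"chem_id", "assay", "auc_med", "auc_lo", "auc_hi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.duplicated(["chem_id", "assay"]).any():
        raise ValueError(f"{path}: duplicate (chem_id, assay) pairs")
    med = df.pivot(index="chem_id", columns="assay", values="auc_med")
    lo = df.pivot(index="chem_id", columns="assay", values="auc_lo")
    hi = df.pivot(index="chem_id", columns="assay", values="auc_hi")
    n_missing = int(med.isna().sum().sum())
    if n_missing:
        logger.warning("%s: %d missing chemical-assay AUC values", path, n_missing)
    return AssayAUCTable(med, lo, hi)


def load_model_spec(path: str | Path) -> ModelSpec:
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, Mapping) or "assays" not in payload:
        raise ValueError(f"{path}: model spec must be a mapping with an 'assays' key")
    return ModelSpec(
        assay_names=list(payload["assays"]),
        weights=[float(w) for w in payload.get("weights", [1.0] * len(payload["assays"]))],
        activity_threshold=float(payload.get("activity_threshold", 0.1)),
        assay_activity_floor=float(payload.get("assay_activity_floor", 0.0)),
        normalize_weights=bool(payload.get("normalize_weights", True)),
    )


def load_full_model(path: str | Path) -> FullModelReference:
    df = _read_csv(path)
    if "chem_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'chem_id'")
    df["chem_id"] = df["chem_id"].astype(str)
    if "antagonist_flag" in df.columns:
        df["antagonist_flag"] = df["antagonist_flag"].map(_coerce_bool)
    return FullModelReference(df.set_index("chem_id"))


# ---------------------------------------------------------------------------
# joining


@dataclass
class DataBundle:
    """The validated intersection of all input sources, keyed by chem_id."""

    chemicals: list[ChemicalRecord]
    fingerprints: FingerprintMatrix
    aucs: AssayAUCTable
    reference: FullModelReference
    universe_ids: list[str] = field(default_factory=list)
    tested_ids: list[str] = field(default_factory=list)
    missing_fingerprint_ids: list[str] = field(default_factory=list)

    @property
    def overlap_ids(self) -> list[str]:
        tested = set(self.tested_ids)
        return [c for c in self.universe_ids if c in tested]


def join_datasets(
    chemicals: Sequence[ChemicalRecord],
    fingerprints: FingerprintMatrix,
    aucs: AssayAUCTable,
    reference: FullModelReference,
) -> DataBundle:
    """Intersect all sources on chem_id, logging per-source counts.

    Chemicals without a fingerprint row cannot be clustered or mapped; they
    are excluded from the bundle's universe/tested lists and returned in
    ``missing_fingerprint_ids``.  An empty intersection between the tested
    set and the AUC table is a hard error.
    """
    fp_ids = set(fingerprints.chem_ids)
    universe_ids, tested_ids, missing_fp = [], [], []
    for rec in chemicals:
        has_fp = rec.chem_id in fp_ids
        if (rec.in_universe or rec.in_tested_set) and not has_fp:
            missing_fp.append(rec.chem_id)
            continue
        if rec.in_universe:
            universe_ids.append(rec.chem_id)
        if rec.in_tested_set:
            tested_ids.append(rec.chem_id)

    auc_ids = set(aucs.chem_ids)
    tested_with_auc = [c for c in tested_ids if c in auc_ids]
    if tested_ids and not tested_with_auc:
        raise ValueError("tested set and AUC table share no chemicals")
    n_dropped_auc = len(tested_ids) - len(tested_with_auc)
    overlap = len(set(universe_ids) & set(tested_with_auc))
    logger.info(
        "join: universe=%d tested=%d overlap=%d missing_fingerprint=%d missing_auc=%d",
        len(universe_ids), len(tested_with_auc), overlap, len(missing_fp), n_dropped_auc,
    )
    if missing_fp:
        logger.warning("chemicals excluded for missing fingerprints: %s", ", ".join(missing_fp))
    return DataBundle(
        chemicals=list(chemicals),
        fingerprints=fingerprints,
        aucs=aucs,
        reference=reference,
        universe_ids=universe_ids,
        tested_ids=tested_with_auc,
        missing_fingerprint_ids=missing_fp,
    )
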