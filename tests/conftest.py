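import numpy as np
import pandas as pd
import pytest

from erconcord.data_model import ClusterAssignment, FingerprintMatrix
from erconcord.synthetic_data import UniverseSpec, gen_universe


@pytest.fixture(scope="session")
def planted_universe():
    """Five planted blocks of ten chemicals, default bit probabilities."""
    return gen_universe(UniverseSpec(n_clusters=5, cluster_sizes=10, seed=7))


@pytest.fixture(scope="session")
def tight_universe():
    """Noise-free blocks: members identical within a block, masks disjoint."""
    return gen_universe(
        UniverseSpec(
            n_clusters=4,
            cluster_sizes=6,
            n_features=64,
            mask_size=8,
            within_profile_on_prob=1.0,
            background_on_prob=0.0,
            seed=3,
        )
    )


def make_fps(bit_rows, ids=None, prefix="C"):
    bits = np.asarray(bit_rows)
    if ids is None:
        ids = [f"{prefix}{i + 1}" for i in range(bits.shape[0])]
    features = [f"b{j + 1}" for j in range(bits.shape[1])]
    return FingerprintMatrix(list(ids), features, bits)


def make_preds(rows):
    """Build a prediction frame from per-chemical dicts (chem_id key required)."""
    df = pd.DataFrame(rows).set_index("chem_id")
    defaults = {
        "full_auc": 0.0,
        "full_call": 0,
        "subset_auc_med": 0.0,
        "subset_auc_lo": 0.0,
        "subset_auc_hi": 0.0,
        "subset_call": 0,
        "antagonist_flag": False,
        "n_active_assays": 0,
    }
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
        else:
            df[col] = df[col].fillna(val)
    df["antagonist_flag"] = df["antagonist_flag"].astype(bool)
    if "confusion_label" not in df.columns:
        df["confusion_label"] = [
            {(1, 1): "TP", (0, 0): "TN", (0, 1): "FP", (1, 0): "FN"}[(f, s)]
            for f, s in zip(df["full_call"], df["subset_call"])
        ]
    return df


def trivial_assignment(chem_ids, cluster_id=1):
    return ClusterAssignment({c: cluster_id for c in chem_ids})
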