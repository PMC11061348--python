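import numpy as np
import pandas as pd
import pytest

from erconcord.concordance import (
    cluster_confusion,
    global_discrepancy_table,
    partition_by_prevalence,
)
from erconcord.data_model import ClusterAssignment

from .conftest import make_preds


def preds_with_labels(labels, **extra):
    rows = []
    for i, lab in enumerate(labels):
        full, subset = {"TP": (1, 1), "TN": (0, 0), "FP": (0, 1), "FN": (1, 0)}[lab]
        row = {
            "chem_id": f"C{i + 1:03d}",
            "full_call": full,
            "subset_call": subset,
            "full_auc": 0.4 * full,
            "subset_auc_med": 0.4 * subset,
        }
        for k, v in extra.items():
            row[k] = v[i] if isinstance(v, (list, np.ndarray)) else v
        rows.append(row)
    return make_preds(rows)


def one_cluster(preds):
    return ClusterAssignment({c: 1 for c in preds.index})


class TestClusterConfusion:
    def test_nine_concordant_one_false_positive(self):
        # a 10-chemical cluster where the subset model calls the lone
        # reference-inactive chemical active: accuracy 90%, sensitivity 100%,
        # specificity 0, balanced accuracy 50%
        preds = preds_with_labels(["TP"] * 9 + ["FP"])
        stats, _ = cluster_confusion(preds, one_cluster(preds))
        row = stats.iloc[0]
        assert row["n"] == 10
        assert (row["tp"], row["fp"], row["tn"], row["fn"]) == (9, 1, 0, 0)
        assert row["accuracy"] == pytest.approx(0.90)
        assert row["sensitivity"] == pytest.approx(1.0)
        assert row["specificity"] == pytest.approx(0.0)
        assert row["balanced_accuracy"] == pytest.approx(0.50)
        assert row["prevalence"] == pytest.approx(0.9)

    def test_all_true_negative_cluster_uses_na_not_zero(self):
        preds = preds_with_labels(["TN"] * 4)
        stats, _ = cluster_confusion(preds, one_cluster(preds))
        row = stats.iloc[0]
        assert row["specificity"] == pytest.approx(1.0)
        assert np.isnan(row["sensitivity"])
        assert np.isnan(row["balanced_accuracy"])
        assert np.isnan(row["ppv"])
        assert row["prevalence"] == 0.0

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(23)
        labels = rng.choice(["TP", "FP", "TN", "FN"], size=30)
        preds = preds_with_labels(labels)
        raw = rng.integers(1, 5, 30)
        assign = ClusterAssignment(
            {c: int(k) for c, k in zip(preds.index, pd.factorize(raw)[0] + 1)}
        )
        stats, below = cluster_confusion(preds, assign, min_cluster_n=1)
        for _, row in stats.iterrows():
            members = [c for c in preds.index if assign.labels[c] == row["cluster_id"]]
            counts = {lab: 0 for lab in ("TP", "FP", "TN", "FN")}
            for c in members:
                counts[preds.loc[c, "confusion_label"]] += 1
            assert (row["tp"], row["fp"], row["tn"], row["fn"]) == (
                counts["TP"], counts["FP"], counts["TN"], counts["FN"]
            )
            assert row["n"] == len(members)

    def test_conservation_across_floor(self):
        """Counts in retained clusters plus below-floor chemicals equal the
        global confusion counts."""
        rng = np.random.default_rng(31)
        labels = rng.choice(["TP", "FP", "TN", "FN"], size=40, p=[0.2, 0.1, 0.6, 0.1])
        preds = preds_with_labels(labels)
        raw = rng.integers(1, 15, 40)
        assign = ClusterAssignment(
            {c: k for c, k in zip(preds.index, pd.factorize(raw)[0] + 1)}
        )
        stats, below = cluster_confusion(preds, assign, min_cluster_n=2)
        total = {lab: int((preds["confusion_label"] == lab).sum()) for lab in ("TP", "FP", "TN", "FN")}
        from_stats = {lab.upper(): int(stats[lab.lower()].sum()) for lab in ("tp", "fp", "tn", "fn")}
        from_below = {lab: int((below["confusion_label"] == lab).sum()) for lab in ("TP", "FP", "TN", "FN")}
        for lab in total:
            assert from_stats[lab.upper() if lab.isupper() else lab] + from_below[lab] == total[lab]

    def test_singletons_listed_separately(self):
        preds = preds_with_labels(["TP", "TP", "FP"])
        assign = ClusterAssignment({"C001": 1, "C002": 1, "C003": 2})
        stats, below = cluster_confusion(preds, assign, min_cluster_n=2)
        assert list(stats["cluster_id"]) == [1]
        assert list(below["chem_id"]) == ["C003"]
        assert list(below["confusion_label"]) == ["FP"]

    def test_unassigned_chemical_is_error(self):
        preds = preds_with_labels(["TP", "TN"])
        assign = ClusterAssignment({"C001": 1})
        with pytest.raises(ValueError, match="without a cluster"):
            cluster_confusion(preds, assign)

    def test_identical_models_give_perfect_clusters(self):
        preds = preds_with_labels(["TP", "TP", "TN", "TN", "TN"])
        preds["subset_auc_med"] = preds["full_auc"]
        assign = ClusterAssignment(
            {c: (1 if i < 3 else 2) for i, c in enumerate(preds.index)}
        )
        stats, _ = cluster_confusion(preds, assign)
        assert (stats["accuracy"] == 1.0).all()
        assert np.allclose(stats["mean_auc_diff"], 0.0)

    def test_balanced_accuracy_equals_accuracy_under_symmetry(self):
        # prevalence 1/2 with one error of each kind: both metrics 0.75
        preds = preds_with_labels(["TP", "TP", "TP", "FN", "TN", "TN", "TN", "FP"])
        stats, _ = cluster_confusion(preds, one_cluster(preds))
        row = stats.iloc[0]
        assert row["balanced_accuracy"] == pytest.approx(row["accuracy"]) == 0.75


class TestPartitionByPrevalence:
    def test_single_all_tn_cluster_is_prev0_perfect(self):
        preds = preds_with_labels(["TN", "TN"])
        stats, _ = cluster_confusion(preds, one_cluster(preds))
        part = partition_by_prevalence(stats).set_index("group")
        assert part.loc["prev0_perfect", "n_clusters"] == 1
        assert part["n_clusters"].sum() == 1

    def test_mixed_cluster(self):
        preds = preds_with_labels(["TP", "TN"])
        stats, _ = cluster_confusion(preds, one_cluster(preds))
        part = partition_by_prevalence(stats).set_index("group")
        assert part.loc["mixed", "n_clusters"] == 1

    def test_planted_group_counts(self):
        rng = np.random.default_rng(7)
        plan = {"prev0_perfect": 6, "prev0_with_fp": 3, "mixed": 4, "prev1": 2}
        labels, cluster_of = [], {}
        cid = 0
        for group, n_clusters in plan.items():
            for _ in range(n_clusters):
                cid += 1
                members = {
                    "prev0_perfect": ["TN", "TN"],
                    "prev0_with_fp": ["TN", "FP"],
                    "mixed": ["TP", "TN", "FN"],
                    "prev1": ["TP", "TP"],
                }[group]
                for lab in members:
                    cluster_of[f"C{len(labels) + 1:03d}"] = cid
                    labels.append(lab)
        preds = preds_with_labels(labels)
        assign = ClusterAssignment(cluster_of)
        stats, _ = cluster_confusion(preds, assign)
        part = partition_by_prevalence(stats).set_index("group")
        for group, n_clusters in plan.items():
            assert part.loc[group, "n_clusters"] == n_clusters


class TestGlobalDiscrepancy:
    def test_no_discrepancies(self):
        preds = preds_with_labels(["TP", "TN", "TN"])
        table = global_discrepancy_table(preds)
        assert table["fp"] == table["fn"] == table["n_discrepant"] == 0
        assert np.isnan(table["median_fp_subset_auc"])

    def test_hand_built_medians(self):
        preds = preds_with_labels(
            ["TP", "TN", "FP", "FP", "TN", "TN"],
            subset_auc_med=[0.5, 0.01, 0.12, 0.18, 0.02, 0.0],
            full_auc=[0.4, 0.05, 0.02, 0.06, 0.01, 0.0],
        )
        preds.loc[preds["confusion_label"] == "FP", "subset_call"] = 1
        table = global_discrepancy_table(preds)
        assert table["fp"] == 2
        assert table["median_fp_subset_auc"] == pytest.approx(0.15)
        assert table["median_fp_full_auc"] == pytest.approx(0.04)

    def test_fn_listing(self):
        preds = preds_with_labels(
            ["FN", "TP"], subset_auc_med=[0.098, 0.5], full_auc=[0.2, 0.4]
        )
        table = global_discrepancy_table(preds)
        assert table["fn"] == 1
        fn = table["fn_chemicals"]
        assert list(fn["chem_id"]) == ["C001"]
        assert fn.iloc[0]["subset_auc_med"] == pytest.approx(0.098)
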