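import numpy as np
import pandas as pd
import pytest

from erconcord.data_model import (
    AssayAUCTable,
    ChemicalRecord,
    ClusterAssignment,
    FingerprintMatrix,
    FullModelReference,
    ModelSpec,
    join_datasets,
    load_assay_aucs,
    load_chemicals,
    load_fingerprints,
    load_full_model,
    load_model_spec,
    write_chemicals,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadChemicals:
    def test_reads_unique_rows(self, tmp_path):
        p = _write(tmp_path, "c.csv", "chem_id,name\nA,x\nB,y\nC,z\n")
        recs = load_chemicals(p)
        assert [r.chem_id for r in recs] == ["A", "B", "C"]

    def test_duplicates_collapse_to_first_with_warning(self, tmp_path, caplog):
        p = _write(tmp_path, "c.csv", "chem_id,name\nA,x\nA,y\nB,z\n")
        with caplog.at_level("WARNING", logger="erconcord"):
            recs = load_chemicals(p)
        assert [r.chem_id for r in recs] == ["A", "B"]
        assert recs[0].name == "x"
        assert any("duplicate" in m for m in caplog.messages)

    def test_missing_optional_columns_default_empty(self, tmp_path):
        p = _write(tmp_path, "c.csv", "chem_id\nA\n")
        (rec,) = load_chemicals(p)
        assert rec.smiles == "" and rec.casrn == "" and not rec.in_universe

    def test_missing_chem_id_column_is_error(self, tmp_path):
        p = _write(tmp_path, "c.csv", "name\nfoo\n")
        with pytest.raises(ValueError, match="chem_id"):
            load_chemicals(p)

    def test_empty_file_is_error(self, tmp_path):
        p = _write(tmp_path, "c.csv", "chem_id,name\n")
        with pytest.raises(ValueError):
            load_chemicals(p)

    def test_membership_flags_parsed(self, tmp_path):
        p = _write(
            tmp_path, "c.csv",
            "chem_id,in_universe,in_tested_set\nA,True,False\nB,1,1\nC,no,yes\n",
        )
        recs = load_chemicals(p)
        assert [(r.in_universe, r.in_tested_set) for r in recs] == [
            (True, False), (True, True), (False, True),
        ]


class TestLoadFingerprints:
    def test_small_matrix(self, tmp_path):
        p = _write(tmp_path, "f.csv", "chem_id,b1,b2,b3,b4\nA,0,1,1,0\nB,1,0,0,1\n")
        fps = load_fingerprints(p)
        assert fps.bits.shape == (2, 4)
        assert fps.bits.tolist() == [[0, 1, 1, 0], [1, 0, 0, 1]]

    def test_non_binary_cell_error_names_row_and_column(self, tmp_path):
        p = _write(tmp_path, "f.csv", "chem_id,b1,b2\nA,0,1\nB,2,0\n")
        with pytest.raises(ValueError, match="chem_id=B.*column=b1"):
            load_fingerprints(p)

    def test_standard_width_roundtrip(self, tmp_path):
        # the fingerprint library in routine use has 729 substructure bits
        rng = np.random.default_rng(0)
        bits = rng.integers(0, 2, size=(3, 729))
        cols = "chem_id," + ",".join(f"bit{j}" for j in range(729))
        rows = "\n".join(f"X{i}," + ",".join(map(str, bits[i])) for i in range(3))
        p = _write(tmp_path, "f.csv", cols + "\n" + rows + "\n")
        fps = load_fingerprints(p)
        assert len(fps.feature_names) == 729
        assert (fps.bits == bits).all()


class TestContainers:
    def test_fingerprint_invariants(self):
        with pytest.raises(ValueError, match="0 or 1"):
            FingerprintMatrix(["A"], ["b1"], np.array([[2]]))
        with pytest.raises(ValueError, match="unique"):
            FingerprintMatrix(["A", "A"], ["b1"], np.zeros((2, 1), dtype=int))

    def test_cluster_assignment_requires_contiguous_ids(self):
        with pytest.raises(ValueError, match="contiguous"):
            ClusterAssignment({"A": 1, "B": 3})
        ClusterAssignment({"A": 1, "B": 2, "C": 1})  # fine

    def test_auc_table_rejects_inverted_ci(self):
        idx = pd.Index(["A"], name="chem_id")
        med = pd.DataFrame({"a1": [0.5]}, index=idx)
        lo = pd.DataFrame({"a1": [0.6]}, index=idx)
        hi = pd.DataFrame({"a1": [0.7]}, index=idx)
        with pytest.raises(ValueError, match="CI ordering"):
            AssayAUCTable(med, lo, hi)

    def test_model_spec_invariants(self):
        with pytest.raises(ValueError):
            ModelSpec(["a", "b"], [1.0])
        with pytest.raises(ValueError):
            ModelSpec(["a"], [0.0])
        with pytest.raises(ValueError):
            ModelSpec(["a"], [-1.0])

    def test_full_model_reference_bounds(self):
        df = pd.DataFrame({"full_auc": [1.2], "antagonist_flag": [False]}, index=["A"])
        with pytest.raises(ValueError):
            FullModelReference(df)


class TestRoundTrip:
    def test_chemicals_roundtrip_bit_exact(self, tmp_path):
        recs = [
            ChemicalRecord("A", casrn="50-00-0", name="x", smiles="CCO",
                           in_universe=True, in_tested_set=False),
            ChemicalRecord("B", in_tested_set=True),
        ]
        p = tmp_path / "c.csv"
        write_chemicals(recs, p)
        back = load_chemicals(p)
        assert [(r.chem_id, r.casrn, r.smiles, r.in_universe, r.in_tested_set)
                for r in back] == [(r.chem_id, r.casrn, r.smiles, r.in_universe,
                                    r.in_tested_set) for r in recs]

    def test_auc_table_roundtrip_12_significant_digits(self, tmp_path):
        rng = np.random.default_rng(5)
        idx = pd.Index([f"C{i}" for i in range(4)], name="chem_id")
        med = pd.DataFrame(rng.random((4, 3)) * 0.5 + 0.25, index=idx,
                           columns=["a1", "a2", "a3"])
        lo = med - 0.1
        hi = med + 0.1
        table = AssayAUCTable(med, lo, hi)
        p = tmp_path / "a.csv"
        table.write_csv(p)
        back = load_assay_aucs(p)
        np.testing.assert_allclose(
            back.auc_med.loc[idx, ["a1", "a2", "a3"]].to_numpy(),
            med.to_numpy(), rtol=1e-12,
        )

    def test_model_spec_roundtrip(self, tmp_path):
        spec = ModelSpec(["a1", "a2"], [2.0, 1.0], activity_threshold=0.2)
        p = tmp_path / "m.yaml"
        spec.to_yaml(p)
        back = load_model_spec(p)
        assert back.assay_names == spec.assay_names
        assert back.weights == spec.weights
        assert back.activity_threshold == 0.2


def _bundle_inputs():
    chems = [
        ChemicalRecord("U1", in_universe=True),
        ChemicalRecord("U2", in_universe=True, in_tested_set=True),
        ChemicalRecord("T1", in_tested_set=True),
        ChemicalRecord("T2", in_tested_set=True),  # no fingerprint
    ]
    fps = FingerprintMatrix(
        ["U1", "U2", "T1"], ["b1", "b2"], np.array([[1, 0], [0, 1], [1, 1]])
    )
    idx = pd.Index(["U2", "T1"], name="chem_id")
    med = pd.DataFrame({"a1": [0.2, 0.3]}, index=idx)
    aucs = AssayAUCTable(med, med.copy(), med.copy())
    ref = FullModelReference(
        pd.DataFrame({"full_auc": [0.2, 0.3], "antagonist_flag": [False, False]}, index=idx)
    )
    return chems, fps, aucs, ref


class TestJoin:
    def test_counts_and_overlap(self):
        chems, fps, aucs, ref = _bundle_inputs()
        bundle = join_datasets(chems, fps, aucs, ref)
        assert bundle.universe_ids == ["U1", "U2"]
        assert bundle.tested_ids == ["U2", "T1"]
        assert bundle.overlap_ids == ["U2"]

    def test_missing_fingerprint_excluded_and_listed(self):
        chems, fps, aucs, ref = _bundle_inputs()
        bundle = join_datasets(chems, fps, aucs, ref)
        assert bundle.missing_fingerprint_ids == ["T2"]
        # nothing silently dropped: stored + excluded covers all flagged chems
        flagged = [r.chem_id for r in chems if r.in_universe or r.in_tested_set]
        stored = set(bundle.universe_ids) | set(bundle.tested_ids)
        assert stored | set(bundle.missing_fingerprint_ids) == set(flagged)

    def test_disjoint_auc_table_is_error(self):
        chems, fps, _, ref = _bundle_inputs()
        idx = pd.Index(["Z9"], name="chem_id")
        med = pd.DataFrame({"a1": [0.1]}, index=idx)
        disjoint = AssayAUCTable(med, med.copy(), med.copy())
        with pytest.raises(ValueError, match="no chemicals"):
            join_datasets(chems, fps, disjoint, ref)


def test_load_full_model_parses_flags(tmp_path):
    p = tmp_path / "fm.csv"
    p.write_text("chem_id,full_auc,antagonist_flag\nA,0.5,True\nB,0.05,0\n")
    ref = load_full_model(p)
    assert ref.table.loc["A", "antagonist_flag"]
    assert not ref.table.loc["B", "antagonist_flag"]
    assert not ref.has_ci
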