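import numpy as np
import pytest

from hemiconn.core_io import (
    ClinicalRecord,
    Connectome,
    HemisphericPair,
    NodeEntry,
    NodeTable,
    ValidationError,
    read_clinical_table,
    read_connectome,
    split_hemispheres,
    write_clinical_table,
    write_connectome,
)
from hemiconn.synthetic_cohort import GeneratorConfig, simulate_cohort, simulate_template


def _write(path, text):
    path.write_text(text)
    return path


class TestReadConnectome:
    def test_three_node_round_trip_of_stated_weights(self, tmp_path):
        text = "\tA\tB\tC\nA\t0\t2\t0\nB\t2\t0\t5\nC\t0\t5\t0\n"
        conn = read_connectome(_write(tmp_path / "m.tsv", text))
        assert conn.nodes.labels == ["A", "B", "C"]
        assert conn.weights[0, 1] == 2 and conn.weights[1, 2] == 5
        assert np.all(np.diag(conn.weights) == 0)

    def test_asymmetric_entry_raises_naming_worst_cell(self, tmp_path):
        text = "\tA\tB\tC\nA\t0\t2\t0\nB\t2\t0\t5\nC\t0\t5.5\t0\n"
        with pytest.raises(ValidationError, match="asymmetric"):
            read_connectome(_write(tmp_path / "m.tsv", text))

    def test_negative_weight_rejected(self, tmp_path):
        text = "\tA\tB\nA\t0\t-1\nB\t-1\t0\n"
        with pytest.raises(ValidationError, match="negative"):
            read_connectome(_write(tmp_path / "m.tsv", text))

    def test_label_mismatch_lists_differences(self, tmp_path, toy_table):
        text = "\tX\tY\nX\t0\t1\nY\t1\t0\n"
        with pytest.raises(ValidationError, match="missing"):
            read_connectome(_write(tmp_path / "m.tsv", text), nodes=toy_table)

    def test_default_synthetic_whole_brain_file_has_79_labels(self, tmp_path):
        conn = simulate_template(GeneratorConfig(seed=0))
        path = tmp_path / "template.tsv"
        write_connectome(conn, path)
        loaded = read_connectome(path)
        assert loaded.n_nodes == 79


class TestWriteConnectome:
    def test_round_trip_identity(self, tmp_path, toy_connectome):
        path = tmp_path / "m.tsv"
        write_connectome(toy_connectome, path)
        again = read_connectome(path, nodes=toy_connectome.nodes)
        assert np.allclose(again.weights, toy_connectome.weights, atol=1e-12)

    def test_zeros_written_explicitly_dense(self, tmp_path, toy_connectome):
        path = tmp_path / "m.tsv"
        write_connectome(toy_connectome, path)
        body = path.read_text().splitlines()[1:]
        # dense contract: every row has one label + 7 numeric cells
        assert all(len(line.split("\t")) == 8 for line in body)
        assert "0" in body[0].split("\t")

    def test_hemispheric_matrix_writes_41_rows(self, tmp_path):
        conn = simulate_template(GeneratorConfig(seed=0))
        pair = split_hemispheres(conn, "left")
        path = tmp_path / "hemi.tsv"
        write_connectome(pair.ipsi, path)
        assert len(path.read_text().splitlines()) == 41


class TestClinicalTable:
    def test_rmt_ratio_derived_from_quotient(self, tmp_path):
        text = (
            "subject_id,lesion_side,subgroup,mrc,nihss,who_grade,"
            "tumor_volume_cm3,rmt_pathological,rmt_healthy\n"
            "s1,left,precentral,5,1,2,10.0,35.13,34.59\n"
        )
        (rec,) = read_clinical_table(_write(tmp_path / "c.csv", text))
        assert rec.rmt_ratio == pytest.approx(35.13 / 34.59)
        assert rec.rmt_ratio == pytest.approx(1.0156, abs=1e-4)

    def test_out_of_range_grade_rejected_with_row_number(self, tmp_path):
        text = (
            "subject_id,lesion_side,subgroup,mrc,nihss,who_grade,"
            "tumor_volume_cm3,rmt_pathological,rmt_healthy\n"
            "s1,left,precentral,5,1,5,10.0,35.13,34.59\n"
        )
        with pytest.raises(ValidationError, match="row 2"):
            read_clinical_table(_write(tmp_path / "c.csv", text))

    def test_cohort_round_trip_preserves_missing_nihss(self, tmp_path):
        cohort = simulate_cohort(GeneratorConfig(seed=5))
        records = [s.clinical for s in cohort.subjects]
        path = tmp_path / "clinical.csv"
        write_clinical_table(records, path)
        loaded = read_clinical_table(path)
        assert len(loaded) == 37
        n_missing = sum(1 for r in loaded if r.nihss is None)
        assert n_missing == sum(1 for r in records if r.nihss is None)

    def test_record_invariants(self):
        with pytest.raises(ValidationError):
            ClinicalRecord("s", "left", (), 6, None, 2, 1.0, 30.0, 30.0)
        with pytest.raises(ValidationError):
            ClinicalRecord("s", "left", (), 5, 43, 2, 1.0, 30.0, 30.0)
        with pytest.raises(ValidationError):
            ClinicalRecord("s", "up", (), 5, None, 2, 1.0, 30.0, 30.0)


class TestSplitHemispheres:
    def test_toy_split_by_manual_enumeration(self, toy_connectome):
        pair = split_hemispheres(toy_connectome, "right")
        # ipsi = rh-a, rh-b, rh-c, brainstem; contra = lh homologs + brainstem
        assert pair.ipsi.nodes.labels == ["rh-a", "rh-b", "rh-c", "brainstem"]
        assert pair.contra.nodes.labels == ["lh-a", "lh-b", "lh-c", "brainstem"]
        # manual enumeration of retained weights
        ipsi_expect = np.zeros((4, 4))
        ipsi_expect[0, 1] = ipsi_expect[1, 0] = 3.0  # rh-a -- rh-b
        ipsi_expect[1, 2] = ipsi_expect[2, 1] = 5.0  # rh-b -- rh-c
        ipsi_expect[2, 3] = ipsi_expect[3, 2] = 9.0  # rh-c -- brainstem
        contra_expect = np.zeros((4, 4))
        contra_expect[0, 1] = contra_expect[1, 0] = 2.0
        contra_expect[0, 2] = contra_expect[2, 0] = 1.0
        contra_expect[1, 2] = contra_expect[2, 1] = 4.0
        contra_expect[2, 3] = contra_expect[3, 2] = 8.0
        assert np.array_equal(pair.ipsi.weights, ipsi_expect)
        assert np.array_equal(pair.contra.weights, contra_expect)

    def test_interhemispheric_weights_absent_from_both_outputs(self, toy_connectome):
        pair = split_hemispheres(toy_connectome, "left")
        excluded = {7.0, 6.0}  # the two interhemispheric weights
        present = set(pair.ipsi.weights.ravel()) | set(pair.contra.weights.ravel())
        assert not (excluded & present)

    def test_edge_weight_conservation(self, toy_connectome):
        """ipsi + contra totals = whole-brain total minus interhemispheric."""
        pair = split_hemispheres(toy_connectome, "left")
        total = toy_connectome.weights.sum() / 2
        inter = 7.0 + 6.0
        split_total = (pair.ipsi.weights.sum() + pair.contra.weights.sum()) / 2
        assert split_total == pytest.approx(total - inter)

    def test_lesion_side_controls_assignment(self, toy_connectome):
        right = split_hemispheres(toy_connectome, "right")
        left = split_hemispheres(toy_connectome, "left")
        assert np.array_equal(right.ipsi.weights, left.contra.weights)
        assert np.array_equal(right.contra.weights, left.ipsi.weights)

    def test_mirror_symmetric_input_gives_identical_halves(self):
        pair = split_hemispheres(simulate_template(GeneratorConfig(seed=2)), "right")
        assert np.allclose(pair.ipsi.weights, pair.contra.weights)

    def test_outputs_are_valid_connectomes(self, toy_connectome):
        pair = split_hemispheres(toy_connectome, "right")
        for conn in (pair.ipsi, pair.contra):
            assert np.allclose(conn.weights, conn.weights.T)
            assert np.all(np.diag(conn.weights) == 0)
        lateral_ipsi = set(pair.ipsi.nodes.labels) - {"brainstem"}
        lateral_contra = set(pair.contra.nodes.labels) - {"brainstem"}
        assert not (lateral_ipsi & lateral_contra)

    def test_atlas_without_bijection_or_brainstem_rejected(self):
        entries = (
            NodeEntry("lh-a", "left", "cortical"),
            NodeEntry("rh-a", "right", "cortical"),
        )
        table = NodeTable(entries, {"lh-a": "rh-a"})
        conn = Connectome(table, np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValidationError, match="midline"):
            split_hemispheres(conn, "left")
        entries3 = entries + (NodeEntry("brainstem", "midline", "brainstem"),)
        table3 = NodeTable(entries3, {})
        conn3 = Connectome(table3, np.zeros((3, 3)))
        with pytest.raises(ValidationError, match="bijection"):
            split_hemispheres(conn3, "left")


class TestNodeTable:
    def test_duplicate_labels_rejected(self):
        entries = (
            NodeEntry("x", "left", "cortical"),
            NodeEntry("x", "right", "cortical"),
        )
        with pytest.raises(ValidationError, match="duplicate"):
            NodeTable(entries, {})

    def test_homolog_map_must_link_left_to_right(self):
        entries = (
            NodeEntry("lh-a", "left", "cortical"),
            NodeEntry("rh-a", "right", "cortical"),
        )
        with pytest.raises(ValidationError):
            NodeTable(entries, {"rh-a": "lh-a"})

    def test_misaligned_pair_rejected(self, toy_connectome):
        pair = split_hemispheres(toy_connectome, "left")
        scrambled = NodeTable(
            (
                NodeEntry("rh-b", "right", "cortical"),
                NodeEntry("rh-a", "right", "cortical"),
                NodeEntry("rh-c", "right", "cortical"),
                NodeEntry("brainstem", "midline", "brainstem"),
            ),
            {},
        )
        bad = Connectome(scrambled, np.zeros((4, 4)))
        with pytest.raises(ValidationError, match="aligned"):
            HemisphericPair(pair.ipsi, bad, "left")
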