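import numpy as np
import pytest

from chemoprofile.datatypes import ActivityRecord, AnnotationCategory, AnnotationSet, Compound, DataType, Target
from chemoprofile.heatmap import (
    Cell,
    build_matrix,
    collapse_columns,
    export_json,
    export_tsv,
    fill_gaps,
    import_json,
    import_tsv,
)
from chemoprofile.qsar import CvPerformance, QsarEnsemble, QsarModel, QsarModelSpec
from chemoprofile.scaffolds import build_forest
from chemoprofile.standardization import compute_zscores, orient_records


def zrec(cid, tid, dt, value, z):
    rec = ActivityRecord(cid, tid, dt, value)
    rec.oriented_value = value
    rec.z_score = z
    return rec


def dfs_oracle(forest):
    """Independent recursive traversal: own members, then children."""
    out = []

    def walk(smiles):
        node = forest.index[smiles]
        child_members = set()
        for c in node.children:
            child_members |= forest.index[c].members
        out.extend(sorted(node.members - child_members))
        for c in sorted(node.children):
            walk(c)

    for root in sorted(forest.ring_roots) + sorted(forest.acyclic_roots):
        walk(root)
    return out


@pytest.fixture(scope="module")
def small_matrix(small_bundle):
    records, _ = compute_zscores(
        orient_records([r for r in small_bundle.records])
    )
    forest = build_forest(small_bundle.library)
    return build_matrix(records, forest, small_bundle.targets), forest


class TestBuildMatrix:
    def test_minimal_one_by_one(self):
        compound = Compound("c1", "c1ccccc1")
        forest = build_forest([compound])
        matrix = build_matrix(
            [zrec("c1", "t1", DataType.PKI, 7.0, 0.4)],
            forest,
            [Target("t1", ("enzyme",))],
        )
        assert matrix.cells[("c1", "t1")].value == 0.4
        assert matrix.row_order == ["c1"] and matrix.col_order == ["t1"]

    def test_max_z_across_data_types(self):
        forest = build_forest([Compound("c1", "c1ccccc1")])
        records = [
            zrec("c1", "t1", DataType.IC50, 100.0, 0.4),
            zrec("c1", "t1", DataType.KI, 100.0, 1.2),
        ]
        matrix = build_matrix(records, forest, [Target("t1", ("enzyme",))])
        assert matrix.cells[("c1", "t1")].value == 1.2

    def test_row_order_matches_independent_traversal(self, small_matrix):
        matrix, forest = small_matrix
        assert matrix.row_order == dfs_oracle(forest)

    def test_column_order_follows_family_tree(self, small_matrix, small_bundle):
        matrix, _ = small_matrix
        expected = [
            t.target_id
            for t in sorted(small_bundle.targets, key=lambda t: (t.family_path, t.target_id))
        ]
        assert matrix.col_order == expected

    def test_unknown_compound_is_an_error_listing_offenders(self):
        forest = build_forest([Compound("c1", "c1ccccc1")])
        with pytest.raises(ValueError, match="ghost"):
            build_matrix(
                [zrec("ghost", "t1", DataType.PKI, 7.0, 0.0)],
                forest,
                [Target("t1", ("enzyme",))],
            )


def constant_ensemble(target_id, p=0.75):
    class _Fixed:
        def predict_proba(self, X):
            return np.array([[1 - p, p]] * len(X))

    model = QsarModel(
        spec=QsarModelSpec("path1024", 5.0),
        classifier=_Fixed(),
        performance=CvPerformance(1.0, 1.0),
        weight=1.0,
        n_positives=5,
        n_negatives=5,
    )
    return QsarEnsemble(target_id=target_id, models=[model], n_training_molecules=25, seed=0)


class TestFillGaps:
    def test_fully_measured_matrix_is_unchanged(self, small_matrix, small_bundle):
        matrix, _ = small_matrix
        # default fixture config has missing_fraction 0: no gaps
        ensembles = {t.target_id: constant_ensemble(t.target_id) for t in small_bundle.targets}
        filled, unpredictable = fill_gaps(
            matrix,
            "qsar",
            compounds_by_id=small_bundle.compounds_by_id,
            qsar_ensembles=ensembles,
        )
        assert filled.cells == matrix.cells
        assert unpredictable == []

    def test_single_gap_filled_with_origin_tag(self):
        compounds = [Compound("c1", "c1ccccc1"), Compound("c2", "Cc1ccccc1")]
        forest = build_forest(compounds)
        matrix = build_matrix(
            [zrec("c1", "t1", DataType.PKI, 7.0, 0.5)],
            forest,
            [Target("t1", ("enzyme",))],
        )
        filled, _ = fill_gaps(
            matrix,
            "qsar",
            compounds_by_id={c.compound_id: c for c in compounds},
            qsar_ensembles={"t1": constant_ensemble("t1")},
        )
        new_cells = set(filled.cells) - set(matrix.cells)
        assert new_cells == {("c2", "t1")}
        assert filled.cells[("c2", "t1")].origin == "qsar"
        assert filled.cells[("c2", "t1")].value == 0.75

    def test_measured_cells_immutable_with_missing_data(self, small_bundle):
        from chemoprofile.fixtures import FixtureConfig, generate_all

        bundle = generate_all(
            FixtureConfig(
                n_compounds=40, n_targets=5, missing_fraction=0.3,
                module_size=4, seed=23,
            )
        )
        records, _ = compute_zscores(orient_records(bundle.records))
        forest = build_forest(bundle.library)
        matrix = build_matrix(records, forest, bundle.targets)
        assert len(matrix.cells) < 40 * 5  # gaps exist by construction
        ensembles = {t.target_id: constant_ensemble(t.target_id) for t in bundle.targets}
        filled, _ = fill_gaps(
            matrix, "qsar", compounds_by_id=bundle.compounds_by_id, qsar_ensembles=ensembles
        )
        for key, cell in matrix.cells.items():
            assert filled.cells[key] == cell  # bit-identical measured cells
        assert len(filled.cells) == 40 * 5

    def test_column_without_model_left_empty_and_reported(self):
        compounds = [Compound("c1", "c1ccccc1"), Compound("c2", "Cc1ccccc1")]
        forest = build_forest(compounds)
        matrix = build_matrix(
            [zrec("c1", "t1", DataType.PKI, 7.0, 0.5)],
            forest,
            [Target("t1", ("enzyme",))],
        )
        filled, unpredictable = fill_gaps(
            matrix, "qsar", compounds_by_id={c.compound_id: c for c in compounds},
            qsar_ensembles={},
        )
        assert unpredictable == ["t1"]
        assert filled.cells == matrix.cells


class TestExport:
    def test_one_by_one_tsv_has_header_plus_row(self, tmp_path):
        forest = build_forest([Compound("c1", "c1ccccc1")])
        matrix = build_matrix(
            [zrec("c1", "t1", DataType.PKI, 7.0, 0.4)], forest, [Target("t1", ("e",))]
        )
        export_tsv(matrix, tmp_path / "m.tsv")
        assert (tmp_path / "m.tsv").read_text().rstrip("\n").count("\n") == 1

    def test_tsv_export_import_export_is_byte_idempotent(self, tmp_path, small_matrix):
        matrix, _ = small_matrix
        export_tsv(matrix, tmp_path / "a.tsv")
        reread = import_tsv(tmp_path / "a.tsv")
        export_tsv(reread, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        assert (tmp_path / "a.tsv.origin").read_bytes() == (tmp_path / "b.tsv.origin").read_bytes()

    def test_json_cell_count_matches_sparse_mapping(self, tmp_path, small_matrix):
        import json

        matrix, _ = small_matrix
        export_json(matrix, tmp_path / "m.json")
        obj = json.loads((tmp_path / "m.json").read_text())
        assert len(obj["cells"]) == len(matrix.cells)
        assert obj["scale"]["low_color"] == "blue"
        assert obj["scale"]["high_color"] == "orange"

    def test_json_round_trip_is_lossless(self, tmp_path, small_matrix):
        matrix, _ = small_matrix
        export_json(matrix, tmp_path / "m.json")
        reread = import_json(tmp_path / "m.json")
        assert reread.cells == matrix.cells
        assert reread.row_order == matrix.row_order
        assert reread.col_order == matrix.col_order


class TestCollapseColumns:
    def test_annotation_mode_takes_max_over_member_targets(self):
        forest = build_forest([Compound("c1", "c1ccccc1")])
        records = [
            zrec("c1", "t1", DataType.PKI, 7.0, 0.5),
            zrec("c1", "t2", DataType.PKI, 8.0, 1.5),
        ]
        matrix = build_matrix(
            records, forest, [Target("t1", ("e",)), Target("t2", ("e",))]
        )
        collapsed = collapse_columns(
            matrix,
            [
                AnnotationSet("pathA", AnnotationCategory.PATHWAY, frozenset({"t1", "t2"})),
                AnnotationSet("pathB", AnnotationCategory.PATHWAY, frozenset({"t1"})),
            ],
        )
        assert collapsed.cells[("c1", "pathA")].value == 1.5
        assert collapsed.cells[("c1", "pathB")].value == 0.5
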