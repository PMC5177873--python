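"""Study-database loading, molecule normalization and the detection matrix."""

import numpy as np
import pytest

from cerank.evidence_model import (
    DatabaseError,
    EvidenceLayer,
    Study,
    build_detection_matrix,
    load_study_database,
    load_study_database_json,
    normalize_molecules,
    write_study_database,
)


class TestLoader:
    def test_one_layer_per_study_for_single_kind(self, tmp_path):
        studies = (
            "study_id\tspecies_group\tstudy_group\tphenotype_precise\t"
            "phenotype_classes\tsample_size\tevidence_kinds\n"
            "a\thuman\tother\t1\tability\t10\texpression\n"
            "b\thuman\tother\t0\tlistening\t20\texpression\n"
            "c\tsongbird\tother\t1\tpractice\tNA\tother_molecular\n"
        )
        detections = (
            "study_id\tevidence_kind\tdataset_id\tmolecule\n"
            "a\texpression\t1\tEGR1\nb\texpression\t1\tFOS\nc\tother_molecular\t1\tBDNF\n"
        )
        (tmp_path / "s.tsv").write_text(studies)
        (tmp_path / "d.tsv").write_text(detections)
        loaded_studies, layers = load_study_database(tmp_path / "s.tsv", tmp_path / "d.tsv")
        assert len(loaded_studies) == 3
        assert len(layers) == 3
        assert loaded_studies[2].sample_size is None

    def test_association_and_linkage_split_into_two_layers(self, tiny_db_files):
        studies, layers = load_study_database(*tiny_db_files)
        gm_layers = [l for l in layers if l.study_id == "hgm1"]
        assert {l.layer_kind for l in gm_layers} == {"association", "linkage"}
        assert len(gm_layers) == 2

    def test_multiple_datasets_yield_one_layer_each(self, tmp_path):
        studies = (
            "study_id\tspecies_group\tstudy_group\tphenotype_precise\t"
            "phenotype_classes\tsample_size\tevidence_kinds\n"
            "d\tsongbird\tother\t0\tlistening\t8\texpression\n"
        )
        detections = "study_id\tevidence_kind\tdataset_id\tmolecule\n" + "".join(
            f"d\texpression\td{i}\tEGR1\n" for i in (1, 2, 3)
        )
        (tmp_path / "s.tsv").write_text(studies)
        (tmp_path / "d.tsv").write_text(detections)
        _, layers = load_study_database(tmp_path / "s.tsv", tmp_path / "d.tsv")
        assert len(layers) == 3
        assert len({l.study_id for l in layers}) == 1

    @pytest.mark.parametrize(
        "mutation, message",
        [
            ("dup_study", "duplicate study_id"),
            ("unknown_study", "unknown study_id"),
            ("missing_kind_detections", "no detections"),
        ],
    )
    def test_schema_violations_are_hard_errors(self, tmp_path, mutation, message):
        studies = (
            "study_id\tspecies_group\tstudy_group\tphenotype_precise\t"
            "phenotype_classes\tsample_size\tevidence_kinds\n"
            "a\thuman\tother\t1\tability\t10\texpression\n"
        )
        detections = "study_id\tevidence_kind\tdataset_id\tmolecule\na\texpression\t1\tEGR1\n"
        if mutation == "dup_study":
            studies += "a\thuman\tother\t1\tability\t10\texpression\n"
        elif mutation == "unknown_study":
            detections += "ghost\texpression\t1\tFOS\n"
        elif mutation == "missing_kind_detections":
            studies = studies.replace("\texpression\n", "\texpression,other_molecular\n")
        (tmp_path / "s.tsv").write_text(studies)
        (tmp_path / "d.tsv").write_text(detections)
        with pytest.raises(DatabaseError, match=message):
            load_study_database(tmp_path / "s.tsv", tmp_path / "d.tsv")

    def test_gene_mapping_studies_restricted_to_mapping_kinds(self):
        with pytest.raises(DatabaseError, match="gene_mapping"):
            Study(
                study_id="x",
                species_group="human",
                study_group="gene_mapping",
                phenotype_precise=True,
                phenotype_classes=frozenset({"ability"}),
                sample_size=10,
                evidence_kinds=frozenset({"expression"}),
            )

    def test_round_trip_preserves_studies_and_layers(self, tiny_db_files, tmp_path):
        studies, layers = load_study_database(*tiny_db_files)
        s2, d2 = tmp_path / "s2.tsv", tmp_path / "d2.tsv"
        write_study_database(studies, layers, s2, d2)
        studies_rt, layers_rt = load_study_database(s2, d2)
        assert studies_rt == studies
        assert {(l.layer_id, l.detected) for l in layers_rt} == {
            (l.layer_id, l.detected) for l in layers
        }

    def test_json_loader_matches_tsv_loader(self, tiny_db_files, tmp_path):
        import json

        studies, layers = load_study_database(*tiny_db_files)
        doc = {
            "studies": [
                {
                    "study_id": s.study_id,
                    "species_group": s.species_group,
                    "study_group": s.study_group,
                    "phenotype_precise": int(s.phenotype_precise),
                    "phenotype_classes": ",".join(sorted(s.phenotype_classes)),
                    "sample_size": s.sample_size,
                    "evidence_kinds": ",".join(sorted(s.evidence_kinds)),
                }
                for s in studies
            ],
            "detections": [
                {
                    "study_id": l.study_id,
                    "evidence_kind": l.layer_kind,
                    "dataset_id": l.layer_id.rsplit(":", 1)[-1],
                    "molecule": m,
                }
                for l in layers
                for m in sorted(l.detected)
            ],
        }
        path = tmp_path / "db.json"
        path.write_text(json.dumps(doc))
        studies_j, layers_j = load_study_database_json(path)
        assert studies_j == studies
        assert {(l.layer_id, l.detected) for l in layers_j} == {
            (l.layer_id, l.detected) for l in layers
        }


class TestNormalization:
    def test_gene_symbols_collapse_case_insensitively(self):
        mols = normalize_molecules(["egr1", "EGR1 ", " Egr1"])
        assert len(mols) == 1
        assert mols[0].identifier == "EGR1"
        assert mols[0].kind == "gene"

    def test_biomarkers_take_canonical_lowercase_form(self):
        mols = normalize_molecules(["Cortisol", "DOPAMINE", "bdnf"])
        assert [(m.identifier, m.kind) for m in mols] == [
            ("cortisol", "biomarker"),
            ("dopamine", "biomarker"),
            ("BDNF", "gene"),
        ]

    def test_empty_identifier_is_an_error(self):
        with pytest.raises(DatabaseError, match="empty"):
            normalize_molecules(["  "])


class TestDetectionMatrix:
    def test_disjoint_layers_give_unit_column_sums(self):
        layers = [
            EvidenceLayer("l1", "s", "expression", frozenset({"A", "B"})),
            EvidenceLayer("l2", "s", "expression", frozenset({"C", "D"})),
        ]
        m = build_detection_matrix(layers, ["A", "B", "C", "D"])
        assert len(m.molecules) == 4
        assert m.detection_counts().tolist() == [1, 1, 1, 1]

    def test_within_layer_detection_is_binary(self):
        # repeated mentions collapse before the layer is built (frozenset),
        # and the matrix enforces 0/1 cells
        layer = EvidenceLayer("l1", "s", "expression", frozenset({"X"}))
        m = build_detection_matrix([layer], ["X", "Y"])
        assert m.data.loc["l1", "X"] == 1
        assert list(m.molecules) == ["X"]  # undetected Y excluded

    def test_unknown_detected_identifier_is_an_error(self):
        layer = EvidenceLayer("l9", "s", "expression", frozenset({"ZZZ"}))
        with pytest.raises(DatabaseError, match="ZZZ"):
            build_detection_matrix([layer], ["A"])

    def test_matrix_total_equals_sum_of_layer_set_sizes(self):
        rng = np.random.default_rng(7)
        universe = [f"M{i}" for i in range(30)]
        layers = []
        for i in range(12):
            picks = rng.choice(universe, size=rng.integers(1, 10), replace=True)
            layers.append(
                EvidenceLayer(f"l{i}", "s", "expression", frozenset(picks.tolist()))
            )
        m = build_detection_matrix(layers, universe)
        assert m.values.sum() == sum(len(l.detected) for l in layers)
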