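import textwrap

import pytest

from cerank.evidence_model import EvidenceLayer, Study


@pytest.fixture
def tiny_studies():
    """Three studies: human gene-mapping, human expression, songbird expression."""
    return [
        Study(
            study_id="hgm1",
            species_group="human",
            study_group="gene_mapping",
            phenotype_precise=True,
            phenotype_classes=frozenset({"ability"}),
            sample_size=500,
            evidence_kinds=frozenset({"association", "linkage"}),
        ),
        Study(
            study_id="hex1",
            species_group="human",
            study_group="other",
            phenotype_precise=True,
            phenotype_classes=frozenset({"listening", "practice"}),
            sample_size=20,
            evidence_kinds=frozenset({"expression"}),
        ),
        Study(
            study_id="sb1",
            species_group="songbird",
            study_group="other",
            phenotype_precise=False,
            phenotype_classes=frozenset({"practice"}),
            sample_size=10,
            evidence_kinds=frozenset({"expression"}),
        ),
    ]


@pytest.fixture
def tiny_layers():
    return [
        EvidenceLayer("hgm1:association:1", "hgm1", "association", frozenset({"EGR1", "FOS"})),
        EvidenceLayer("hgm1:linkage:1", "hgm1", "linkage", frozenset({"FOS", "SNCA"})),
        EvidenceLayer("hex1:expression:1", "hex1", "expression", frozenset({"EGR1", "cortisol"})),
        EvidenceLayer("sb1:expression:1", "sb1", "expression", frozenset({"EGR1"})),
    ]


@pytest.fixture
def tiny_db_files(tmp_path):
    """The same three-study database as TSV files on disk."""
    studies = textwrap.dedent(
        """\
        study_id\tspecies_group\tstudy_group\tphenotype_precise\tphenotype_classes\tsample_size\tevidence_kinds
        hgm1\thuman\tgene_mapping\t1\tability\t500\tassociation,linkage
        hex1\thuman\tother\t1\tlistening,practice\t20\texpression
        sb1\tsongbird\tother\t0\tpractice\t10\texpression
        """
    )
    detections = textwrap.dedent(
        """\
        study_id\tevidence_kind\tdataset_id\tmolecule
        hgm1\tassociation\t1\tEGR1
        hgm1\tassociation\t1\tFOS
        hgm1\tlinkage\t1\tFOS
        hgm1\tlinkage\t1\tSNCA
        hex1\texpression\t1\tEGR1
        hex1\texpression\t1\tcortisol
        sb1\texpression\t1\tEGR1
        """
    )
    studies_path = tmp_path / "studies.tsv"
    detections_path = tmp_path / "detections.tsv"
    studies_path.write_text(studies)
    detections_path.write_text(detections)
    return studies_path, detections_path
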