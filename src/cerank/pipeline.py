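"""End-to-end orchestration: load -> map -> translate -> weight -> rank -> characterize.

`prioritize` is the in-memory core used by both the CLI and the synthetic
benchmark; `run_pipeline` adds file IO, logging and a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .ce_rank import (
    CEResult,
    DEFAULT_QUANTILE,
    rank_from_matrix,
    results_frame,
    select_top_quantile,
    stratified_rank,
)
from .enrichment import (
    DEFAULT_MAX_NETWORK_SIZE,
    build_networks,
    enrichment_frame,
    fisher_enrichment,
    networks_frame,
    read_edge_list,
    read_gmt,
)
from .evidence_model import (
    DEFAULT_BIOMARKERS,
    DetectionMatrix,
    EvidenceLayer,
    PHENOTYPE_CLASSES,
    Study,
    _layers_from_records,
    _studies_from_records,
    build_detection_matrix,
    load_study_database,
    load_study_database_json,
    normalize_layers,
)
from .genome_mapping import (
    DEFAULT_FLANK_BP,
    DEFAULT_LINKAGE_HALF_WIDTH_CM,
    GeneAnnotation,
    marker_detections,
    read_markers,
)
from .homology import HomologTable, UnmappedReport, translate_to_human
from .scoring import WeightComponents, score_all_layers, weights_frame

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and tunables of one analysis run.

    Defaults are the analysis constants: +/-500 kb association windows,
    1 cM = 1 Mb linkage conversion, q = 0.995 top-quantile selection and a
    35-node network cap.
    """

    studies: str
    detections: str
    out_dir: str
    homologs: str | None = None
    markers: str | None = None
    annotation_gff3: str | None = None
    annotation_bed: str | None = None
    chrom_sizes: str | None = None
    gene_sets: str | None = None
    edges: str | None = None
    flank_bp: int = DEFAULT_FLANK_BP
    linkage_half_width_cm: float = DEFAULT_LINKAGE_HALF_WIDTH_CM
    quantile: float = DEFAULT_QUANTILE
    phenotype_classes: tuple[str, ...] = PHENOTYPE_CLASSES
    network_max_size: int = DEFAULT_MAX_NETWORK_SIZE
    adjust_pvalues: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "phenotype_classes" in doc:
            doc["phenotype_classes"] = tuple(doc["phenotype_classes"])
        return cls(**doc)

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["phenotype_classes"] = list(self.phenotype_classes)
        return doc

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PrioritizationResult:
    """In-memory outcome of the scoring + ranking core."""

    studies: list[Study]
    layers: list[EvidenceLayer]
    components: dict[str, WeightComponents]
    matrix: DetectionMatrix
    weights: dict[str, float]
    ranking: list[CEResult]
    unmapped: dict[str, UnmappedReport] = field(default_factory=dict)
    dropped_layers: list[str] = field(default_factory=list)

    @property
    def n_unmapped(self) -> int:
        return sum(r.n_unmapped for r in self.unmapped.values())


def prioritize(
    studies: Sequence[Study],
    layers: Sequence[EvidenceLayer],
    homolog_table: HomologTable | None = None,
    biomarkers: frozenset[str] = DEFAULT_BIOMARKERS,
) -> PrioritizationResult:
    """Translate, weight, score and rank one study database.

    Non-human layers are translated through the homolog table (biomarkers
    pass through untranslated); layers whose entire detected set is unmapped
    are dropped with a warning. Weights follow the custom-score scheme; the
    ranking is the deterministic CE ordering.
    """
    by_id = {s.study_id: s for s in studies}
    translated: list[EvidenceLayer] = []
    unmapped: dict[str, UnmappedReport] = {}
    dropped: list[str] = []
    for layer in layers:
        species = by_id[layer.study_id].species_group
        if homolog_table is not None and species != "human":
            human_ids, report = translate_to_human(
                [(species, ident) for ident in sorted(layer.detected)],
                homolog_table,
                passthrough=biomarkers,
            )
            unmapped[layer.layer_id] = report
            if not human_ids:
                logger.warning(
                    "layer %s dropped: no identifier could be mapped to a human homolog",
                    layer.layer_id,
                )
                dropped.append(layer.layer_id)
                continue
            layer = dataclasses.replace(layer, detected=frozenset(human_ids))
        translated.append(layer)
    normalized, molecules = normalize_layers(translated, biomarkers)
    weighted, components = score_all_layers(studies, normalized)
    matrix = build_detection_matrix(weighted, molecules)
    weights = {l.layer_id: l.weight for l in weighted}
    ranking = rank_from_matrix(matrix, weights, studies, weighted)
    return PrioritizationResult(
        studies=list(studies),
        layers=weighted,
        components=components,
        matrix=matrix,
        weights=weights,
        ranking=ranking,
        unmapped=unmapped,
        dropped_layers=dropped,
    )


def _load_inputs(config: PipelineConfig) -> tuple[list[Study], list[EvidenceLayer], int]:
    """Load the study database, merging marker-derived gene detections if given."""
    if config.studies.endswith(".json"):
        studies, layers = load_study_database_json(config.studies)
        if config.markers:
            raise ValueError("marker merging requires the TSV database form")
        return studies, layers, 0
    n_dropped_markers = 0
    if config.markers:
        if not config.chrom_sizes or not (config.annotation_gff3 or config.annotation_bed):
            raise ValueError("markers input requires an annotation and chrom.sizes")
        chrom_lengths = GeneAnnotation.read_chrom_sizes(config.chrom_sizes)
        if config.annotation_gff3:
            annotation = GeneAnnotation.from_gff3(config.annotation_gff3, chrom_lengths)
        else:
            annotation = GeneAnnotation.from_bed(config.annotation_bed, chrom_lengths)
        marker_rows, dropped = marker_detections(
            read_markers(config.markers),
            annotation,
            flank=config.flank_bp,
            half_width_cm=config.linkage_half_width_cm,
        )
        n_dropped_markers = len(dropped)
        studies_df = pd.read_csv(config.studies, sep="\t", dtype=str)
        detections_df = pd.read_csv(config.detections, sep="\t", dtype=str)
        if "dataset_id" not in detections_df.columns:
            detections_df["dataset_id"] = "1"
        detections_df = pd.concat([detections_df, marker_rows], ignore_index=True)
        studies = _studies_from_records(studies_df.to_dict("records"))
        layers = _layers_from_records(studies, detections_df.to_dict("records"))
        return studies, layers, n_dropped_markers
    studies, layers = load_study_database(config.studies, config.detections)
    return studies, layers, 0


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis and write all outputs under `config.out_dir`.

    Outputs: weights.tsv, ranks.tsv, top_set.tsv, ranks_<class>.tsv per
    stratified subphenotype, enrichment.tsv / networks.tsv when gene sets /
    edges are supplied, and manifest.json. Identical inputs and config
    produce byte-identical outputs.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    studies, layers, n_dropped_markers = _load_inputs(config)
    table = HomologTable.from_tsv(config.homologs) if config.homologs else None
    result = prioritize(studies, layers, table)

    weights_frame(result.components).to_csv(
        out / "weights.tsv", sep="\t", index=False, float_format="%.6f"
    )
    results_frame(result.ranking).to_csv(out / "ranks.tsv", sep="\t", index=False)
    top = select_top_quantile(result.ranking, config.quantile)
    results_frame(top).to_csv(out / "top_set.tsv", sep="\t", index=False)

    for cls in config.phenotype_classes:
        strat = stratified_rank(
            studies, result.layers, result.matrix, result.weights, cls
        )
        results_frame(strat).to_csv(out / f"ranks_{cls}.tsv", sep="\t", index=False)

    top_molecules = [r.molecule for r in top]
    if config.gene_sets:
        gene_sets = read_gmt(config.gene_sets)
        universe = set(result.matrix.molecules)
        enr = fisher_enrichment(
            top_molecules, gene_sets, universe, adjust=config.adjust_pvalues
        )
        enrichment_frame(enr).to_csv(
            out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
        )
    if config.edges:
        nets = build_networks(
            top_molecules, read_edge_list(config.edges), config.network_max_size
        )
        networks_frame(nets).to_csv(out / "networks.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": {
            "studies": len(studies),
            "layers": len(result.layers),
            "molecules": len(result.matrix.molecules),
            "unmapped_identifiers": result.n_unmapped,
            "dropped_layers": len(result.dropped_layers),
            "dropped_markers": n_dropped_markers,
            "top_set": len(top),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
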