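"""Study database model: studies, evidence layers, molecules and the detection matrix.

A *study* is one curated publication with species, phenotype and sample-size
metadata. Each study casts votes through one or more *evidence layers*: one
layer per evidence kind (association, linkage, expression, other molecular)
per independent dataset. A layer holds the set of molecules (genes and
biomarkers) it detected; the binary layer-by-molecule detection matrix is
the input to the convergent-evidence score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECIES_GROUPS = frozenset({"human", "songbird", "other_animal"})
STUDY_GROUPS = frozenset({"gene_mapping", "other"})
PHENOTYPE_CLASSES = ("listening", "ability", "practice")
EVIDENCE_KINDS = ("association", "linkage", "expression", "other_molecular")
GENE_MAPPING_KINDS = frozenset({"association", "linkage"})

#: Controlled vocabulary of non-gene analytes (hormones, neurotransmitters)
#: tracked alongside genes. Matched case-insensitively; canonical form is
#: lower-case.
DEFAULT_BIOMARKERS = frozenset(
    {
        "cortisol",
        "corticosterone",
        "dopamine",
        "noradrenalin",
        "adrenalin",
        "serotonin",
        "estradiol",
        "testosterone",
        "oxytocin",
        "prolactin",
    }
)

STUDIES_COLUMNS = [
    "study_id",
    "species_group",
    "study_group",
    "phenotype_precise",
    "phenotype_classes",
    "sample_size",
    "evidence_kinds",
]
DETECTIONS_COLUMNS = ["study_id", "evidence_kind", "dataset_id", "molecule"]


class DatabaseError(ValueError):
    """Raised when the study database violates its schema or invariants."""


@dataclass(frozen=True)
class Study:
    """One curated publication contributing evidence layers."""

    study_id: str
    species_group: str
    study_group: str
    phenotype_precise: bool
    phenotype_classes: frozenset[str]
    sample_size: int | None
    evidence_kinds: frozenset[str]

    def __post_init__(self) -> None:
        if not self.study_id:
            raise DatabaseError("study_id must be non-empty")
        if self.species_group not in SPECIES_GROUPS:
            raise DatabaseError(
                f"study {self.study_id!r}: unknown species_group {self.species_group!r}"
            )
        if self.study_group not in STUDY_GROUPS:
            raise DatabaseError(
                f"study {self.study_id!r}: unknown study_group {self.study_group!r}"
            )
        if not self.phenotype_classes:
            raise DatabaseError(f"study {self.study_id!r}: phenotype_classes empty")
        bad = self.phenotype_classes - set(PHENOTYPE_CLASSES)
        if bad:
            raise DatabaseError(
                f"study {self.study_id!r}: unknown phenotype classes {sorted(bad)}"
            )
        if not self.evidence_kinds:
            raise DatabaseError(f"study {self.study_id!r}: evidence_kinds empty")
        bad = self.evidence_kinds - set(EVIDENCE_KINDS)
        if bad:
            raise DatabaseError(
                f"study {self.study_id!r}: unknown evidence kinds {sorted(bad)}"
            )
        if self.study_group == "gene_mapping" and not self.evidence_kinds <= GENE_MAPPING_KINDS:
            raise DatabaseError(
                f"study {self.study_id!r}: gene_mapping studies may only carry "
                f"association/linkage evidence, got {sorted(self.evidence_kinds)}"
            )
        if self.sample_size is not None and self.sample_size <= 0:
            raise DatabaseError(
                f"study {self.study_id!r}: sample_size must be positive"
            )


@dataclass
class EvidenceLayer:
    """One vote-casting unit: a (study, evidence kind, dataset) triple.

    ``detected`` holds molecule identifiers; for non-human studies these are
    species-native identifiers until translated through the homolog table.
    ``weight`` is the layer's custom score w_i, unset until scoring.
    """

    layer_id: str
    study_id: str
    layer_kind: str
    detected: frozenset[str]
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.layer_kind not in EVIDENCE_KINDS:
            raise DatabaseError(
                f"layer {self.layer_id!r}: unknown layer_kind {self.layer_kind!r}"
            )
        if not self.detected:
            raise DatabaseError(f"layer {self.layer_id!r}: empty detected set")
        if self.weight is not None and not 0.0 < self.weight <= 1.0:
            raise DatabaseError(
                f"layer {self.layer_id!r}: weight {self.weight} outside (0, 1]"
            )


@dataclass(frozen=True)
class Molecule:
    """A gene symbol or a biomarker analyte, after identifier normalization."""

    identifier: str
    kind: str  # "gene" | "biomarker"
    location: object | None = None  # optional GenomicInterval for genes

    def __post_init__(self) -> None:
        if not self.identifier:
            raise DatabaseError("molecule identifier must be non-empty")
        if self.kind not in ("gene", "biomarker"):
            raise DatabaseError(f"unknown molecule kind {self.kind!r}")
        if self.kind == "biomarker" and self.location is not None:
            raise DatabaseError(
                f"biomarker {self.identifier!r} cannot carry a genomic location"
            )


@dataclass
class DetectionMatrix:
    """Binary layers x molecules indicator matrix e_gi.

    Backed by a pandas DataFrame with layer_ids as the index and molecule
    identifiers as columns; every cell is 0 or 1.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise DatabaseError("detection matrix labels must be unique")
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise DatabaseError("detection matrix cells must be 0 or 1")

    @property
    def layers(self) -> list[str]:
        return list(self.data.index)

    @property
    def molecules(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def detection_counts(self) -> pd.Series:
        """Number of layers detecting each molecule."""
        return self.data.sum(axis=0)


def _split_field(value: str, label: str, context: str) -> frozenset[str]:
    parts = frozenset(p.strip() for p in str(value).split(",") if p.strip())
    if not parts:
        raise DatabaseError(f"{context}: empty {label}")
    return parts


def _parse_bool(value: object, context: str) -> bool:
    text = str(value).strip().lower()
    if text in ("1", "true", "yes"):
        return True
    if text in ("0", "false", "no"):
        return False
    raise DatabaseError(f"{context}: cannot parse boolean {value!r}")


def _parse_sample_size(value: object, context: str) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if text in ("", "NA", "na", "NaN", "nan", "None"):
        return None
    try:
        size = int(float(text))
    except ValueError as exc:
        raise DatabaseError(f"{context}: cannot parse sample_size {value!r}") from exc
    return size


def _studies_from_records(records: Iterable[Mapping[str, object]]) -> list[Study]:
    studies: list[Study] = []
    seen: set[str] = set()
    for rec in records:
        sid = str(rec["study_id"]).strip()
        if sid in seen:
            raise DatabaseError(f"duplicate study_id {sid!r}")
        seen.add(sid)
        studies.append(
            Study(
                study_id=sid,
                species_group=str(rec["species_group"]).strip(),
                study_group=str(rec["study_group"]).strip(),
                phenotype_precise=_parse_bool(rec["phenotype_precise"], f"study {sid!r}"),
                phenotype_classes=_split_field(
                    rec["phenotype_classes"], "phenotype_classes", f"study {sid!r}"
                ),
                sample_size=_parse_sample_size(rec.get("sample_size"), f"study {sid!r}"),
                evidence_kinds=_split_field(
                    rec["evidence_kinds"], "evidence_kinds", f"study {sid!r}"
                ),
            )
        )
    return studies


def _layers_from_records(
    studies: Sequence[Study], records: Iterable[Mapping[str, object]]
) -> list[EvidenceLayer]:
    by_id = {s.study_id: s for s in studies}
    # (study_id, kind, dataset) -> detected identifiers, insertion-ordered
    groups: dict[tuple[str, str, str], list[str]] = {}
    kinds_seen: dict[str, set[str]] = {s.study_id: set() for s in studies}
    for rec in records:
        sid = str(rec["study_id"]).strip()
        study = by_id.get(sid)
        if study is None:
            raise DatabaseError(f"detection row references unknown study_id {sid!r}")
        kind = str(rec["evidence_kind"]).strip()
        if kind not in study.evidence_kinds:
            raise DatabaseError(
                f"detection for study {sid!r} uses undeclared evidence kind {kind!r}"
            )
        dataset = str(rec.get("dataset_id") or "1").strip() or "1"
        molecule = str(rec["molecule"]).strip()
        if not molecule:
            raise DatabaseError(f"study {sid!r}: empty molecule identifier")
        groups.setdefault((sid, kind, dataset), []).append(molecule)
        kinds_seen[sid].add(kind)
    for study in studies:
        missing = study.evidence_kinds - kinds_seen[study.study_id]
        if missing:
            raise DatabaseError(
                f"study {study.study_id!r} declares evidence kinds "
                f"{sorted(missing)} with no detections"
            )
    layers = [
        EvidenceLayer(
            layer_id=f"{sid}:{kind}:{dataset}",
            study_id=sid,
            layer_kind=kind,
            detected=frozenset(detected),
        )
        for (sid, kind, dataset), detected in sorted(groups.items())
    ]
    return layers


def load_study_database(
    studies_path: str | Path, detections_path: str | Path
) -> tuple[list[Study], list[EvidenceLayer]]:
    """Load studies.tsv + detections.tsv into studies and unweighted layers.

    One layer is created per (study, evidence_kind, dataset_id) combination
    present in the detections table; a study reporting both association and
    linkage therefore yields two layers, and a study with several independent
    datasets yields one layer per dataset.
    """
    studies_df = pd.read_csv(studies_path, sep="\t", dtype=str)
    missing = [c for c in STUDIES_COLUMNS if c not in studies_df.columns]
    if missing:
        raise DatabaseError(f"studies table missing columns {missing}")
    detections_df = pd.read_csv(detections_path, sep="\t", dtype=str)
    if "dataset_id" not in detections_df.columns:
        detections_df["dataset_id"] = "1"
    missing = [c for c in DETECTIONS_COLUMNS if c not in detections_df.columns]
    if missing:
        raise DatabaseError(f"detections table missing columns {missing}")
    studies = _studies_from_records(studies_df.to_dict("records"))
    layers = _layers_from_records(studies, detections_df.to_dict("records"))
    return studies, layers


def load_study_database_json(path: str | Path) -> tuple[list[Study], list[EvidenceLayer]]:
    """Load a single JSON document mirroring the two-table TSV schema."""
    with open(path) as fh:
        doc = json.load(fh)
    studies = _studies_from_records(doc["studies"])
    layers = _layers_from_records(studies, doc["detections"])
    return studies, layers


def write_study_database(
    studies: Sequence[Study],
    layers: Sequence[EvidenceLayer],
    studies_path: str | Path,
    detections_path: str | Path,
) -> None:
    """Write studies/layers back to the TSV schema (round-trips with the loader)."""
    rows = [
        {
            "study_id": s.study_id,
            "species_group": s.species_group,
            "study_group": s.study_group,
            "phenotype_precise": int(s.phenotype_precise),
            "phenotype_classes": ",".join(sorted(s.phenotype_classes)),
            "sample_size": "NA" if s.sample_size is None else s.sample_size,
            "evidence_kinds": ",".join(sorted(s.evidence_kinds)),
        }
        for s in studies
    ]
    pd.DataFrame(rows, columns=STUDIES_COLUMNS).to_csv(
        studies_path, sep="\t", index=False
    )
    det_rows = []
    for layer in layers:
        dataset = layer.layer_id.rsplit(":", 1)[-1]
        for mol in sorted(layer.detected):
            det_rows.append(
                {
                    "study_id": layer.study_id,
                    "evidence_kind": layer.layer_kind,
                    "dataset_id": dataset,
                    "molecule": mol,
                }
            )
    pd.DataFrame(det_rows, columns=DETECTIONS_COLUMNS).to_csv(
        detections_path, sep="\t", index=False
    )


def normalize_molecules(
    raw_identifiers: Iterable[str],
    biomarker_vocabulary: Iterable[str] = DEFAULT_BIOMARKERS,
) -> list[Molecule]:
    """Normalize raw identifiers into typed molecules.

    Gene symbols are upper-cased and whitespace-stripped; identifiers matching
    the biomarker vocabulary (case-insensitively) become biomarkers in their
    canonical lower-case form. Duplicates collapse, preserving first-seen
    order.
    """
    vocab = {b.lower() for b in biomarker_vocabulary}
    out: list[Molecule] = []
    seen: set[str] = set()
    for raw in raw_identifiers:
        ident = raw.strip()
        if not ident:
            raise DatabaseError("empty molecule identifier")
        if ident.lower() in vocab:
            mol = Molecule(ident.lower(), "biomarker")
        else:
            mol = Molecule(ident.upper(), "gene")
        if mol.identifier not in seen:
            seen.add(mol.identifier)
            out.append(mol)
    return out


def normalize_layers(
    layers: Sequence[EvidenceLayer],
    biomarker_vocabulary: Iterable[str] = DEFAULT_BIOMARKERS,
) -> tuple[list[EvidenceLayer], list[Molecule]]:
    """Normalize every layer's detected identifiers; return layers + molecule list."""
    all_molecules: dict[str, Molecule] = {}
    normalized: list[EvidenceLayer] = []
    for layer in layers:
        mols = normalize_molecules(sorted(layer.detected), biomarker_vocabulary)
        for mol in mols:
            all_molecules.setdefault(mol.identifier, mol)
        normalized.append(
            replace(layer, detected=frozenset(m.identifier for m in mols))
        )
    return normalized, list(all_molecules.values())


def build_detection_matrix(
    layers: Sequence[EvidenceLayer], molecules: Sequence[Molecule | str]
) -> DetectionMatrix:
    """Materialize the binary e_gi matrix from layers' detected sets.

    Columns are restricted to molecules detected in at least one layer;
    repeated mentions within one layer collapse to a single 1.
    """
    idents = [m.identifier if isinstance(m, Molecule) else m for m in molecules]
    known = set(idents)
    detected_any: set[str] = set()
    for layer in layers:
        for ident in layer.detected:
            if ident not in known:
                raise DatabaseError(
                    f"layer {layer.layer_id!r} detects unknown molecule {ident!r}"
                )
        detected_any |= layer.detected
    columns = [i for i in idents if i in detected_any]
    col_index = {ident: j for j, ident in enumerate(columns)}
    values = np.zeros((len(layers), len(columns)), dtype=np.int8)
    for i, layer in enumerate(layers):
        for ident in layer.detected:
            values[i, col_index[ident]] = 1
    frame = pd.DataFrame(values, index=[l.layer_id for l in layers], columns=columns)
    return DetectionMatrix(frame)
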