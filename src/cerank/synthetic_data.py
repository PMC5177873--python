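"""Planted-signal synthetic study databases for end-to-end benchmarking.

The generator emulates the statistical shape of the curated literature
database the pipeline is built for: roughly a hundred studies split across
human, songbird and other-animal groups; one or two evidence layers per
study; a molecule universe of several thousand symbols; a small set of
*planted* signal molecules that every layer detects with elevated
probability p_signal while background molecules appear with probability
p_noise; and a many-to-many homolog table through which non-human
detections must be translated, with a configurable unmappable fraction.
Detection is independent Bernoulli per (layer, molecule) — the null the
vote count itself assumes. All randomness flows from a single seed.

`recovery_experiment` is the benchmark harness: generate -> weight ->
score -> rank -> select top-K and measure how many planted molecules the
ranking recovers.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evidence_model import EvidenceLayer, Study, write_study_database
from .genome_mapping import GeneAnnotation, GenomicInterval
from .homology import HomologTable
from .pipeline import prioritize

NON_HUMAN_SPECIES = ("songbird", "other_animal")

# Study-group composition mirroring the curated database: 35 human, 55
# songbird and 15 other-animal studies; genome-wide DNA (gene-mapping)
# studies occur in the human group only.
DEFAULT_N_STUDIES = {"human": 35, "songbird": 55, "other_animal": 15}
DEFAULT_CLASS_PROBS = {
    "human": {"listening": 22 / 35, "ability": 16 / 35, "practice": 8 / 35},
    "songbird": {"listening": 27 / 55, "ability": 19 / 55, "practice": 34 / 55},
    "other_animal": {"listening": 10 / 15, "ability": 1 / 15, "practice": 5 / 15},
}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study-database generator."""

    n_studies: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_STUDIES))
    fraction_gene_mapping: float = 10 / 35  # of human studies
    sample_size_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"gene_mapping": (100, 1000), "other": (6, 50)}
    )
    n_molecules: int = 8000
    n_planted: int = 40
    p_signal: float = 0.3
    p_noise: float = 0.01
    homolog_unmapped_rate: float = 0.1
    homolog_duplicate_rate: float = 0.05
    phenotype_precise_prob: float = 0.4
    paired_linkage_prob: float = 0.5    # gene-mapping study also reports linkage
    multi_dataset_prob: float = 0.05    # expression study split into 2 datasets
    class_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_PROBS.items()}
    )
    # toy annotation for the region-to-gene fixtures
    n_chromosomes: int = 2
    chrom_length_bp: int = 5_000_000
    genes_per_chromosome: int = 50
    gene_length_bp: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.p_signal,
            self.p_noise,
            self.homolog_unmapped_rate,
            self.homolog_duplicate_rate,
            self.phenotype_precise_prob,
            self.paired_linkage_prob,
            self.multi_dataset_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_planted > self.n_molecules:
            raise ValueError("n_planted cannot exceed the molecule universe")


@dataclass
class SyntheticDatabase:
    """In-memory generated database plus ground truth."""

    studies: list[Study]
    layers: list[EvidenceLayer]  # unweighted; non-human layers hold native ids
    homologs: HomologTable
    planted: list[str]           # human symbols carrying the signal
    universe: list[str]


def _native_id(species: str, symbol: str) -> str:
    return f"{species[:2]}_{symbol.lower()}"


def generate_database(config: SyntheticConfig) -> SyntheticDatabase:
    """Draw one synthetic study database; deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    universe = [f"G{i:04d}" for i in range(1, config.n_molecules + 1)]
    planted_idx = rng.choice(config.n_molecules, size=config.n_planted, replace=False)
    planted_mask = np.zeros(config.n_molecules, dtype=bool)
    planted_mask[planted_idx] = True
    planted = [universe[i] for i in sorted(planted_idx)]

    # many-to-many homolog table with a deliberately unmappable fraction
    triples: list[tuple[str, str, str]] = []
    for species in NON_HUMAN_SPECIES:
        unmappable = rng.random(config.n_molecules) < config.homolog_unmapped_rate
        duplicated = rng.random(config.n_molecules) < config.homolog_duplicate_rate
        extra = rng.integers(0, config.n_molecules, size=config.n_molecules)
        for j, symbol in enumerate(universe):
            if unmappable[j]:
                continue
            triples.append((species, _native_id(species, symbol), symbol))
            if duplicated[j] and extra[j] != j:
                triples.append((species, _native_id(species, symbol), universe[extra[j]]))
    homologs = HomologTable(triples)

    p_vector = np.where(planted_mask, config.p_signal, config.p_noise)
    studies: list[Study] = []
    layers: list[EvidenceLayer] = []

    def draw_detected(species: str) -> frozenset[str]:
        hits = np.nonzero(rng.random(config.n_molecules) < p_vector)[0]
        if hits.size == 0:  # keep layers non-empty, as the schema requires
            hits = np.array([rng.choice(planted_idx)])
        symbols = (universe[i] for i in hits)
        if species == "human":
            return frozenset(symbols)
        return frozenset(_native_id(species, s) for s in symbols)

    for species, n in config.n_studies.items():
        n_gm = (
            int(round(config.fraction_gene_mapping * n)) if species == "human" else 0
        )
        for i in range(n):
            sid = f"{species}{i + 1:03d}"
            gene_mapping = i < n_gm
            group = "gene_mapping" if gene_mapping else "other"
            lo, hi = config.sample_size_ranges[group]
            size = int(rng.integers(lo, hi + 1))
            classes = frozenset(
                c for c, p in config.class_probs[species].items() if rng.random() < p
            )
            if not classes:
                probs = config.class_probs[species]
                names = sorted(probs)
                w = np.array([probs[c] for c in names])
                classes = frozenset({names[rng.choice(len(names), p=w / w.sum())]})
            if gene_mapping:
                kinds = frozenset(
                    {"association", "linkage"}
                    if rng.random() < config.paired_linkage_prob
                    else {"association"}
                )
            elif species == "songbird":
                kinds = frozenset({rng.choice(["expression", "expression", "other_molecular"])})
            else:
                kinds = frozenset({rng.choice(["expression", "other_molecular"])})
            studies.append(
                Study(
                    study_id=sid,
                    species_group=species,
                    study_group=group,
                    phenotype_precise=bool(rng.random() < config.phenotype_precise_prob),
                    phenotype_classes=classes,
                    sample_size=size,
                    evidence_kinds=kinds,
                )
            )
            for kind in sorted(kinds):
                n_datasets = (
                    2
                    if kind == "expression" and rng.random() < config.multi_dataset_prob
                    else 1
                )
                for d in range(1, n_datasets + 1):
                    layers.append(
                        EvidenceLayer(
                            layer_id=f"{sid}:{kind}:{d}",
                            study_id=sid,
                            layer_kind=kind,
                            detected=draw_detected(species),
                        )
                    )
    return SyntheticDatabase(studies, layers, homologs, planted, universe)


def generate_study_database(
    config: SyntheticConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write studies.tsv, detections.tsv and homologs.tsv; byte-stable per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    db = generate_database(config)
    paths = {
        "studies": out / "studies.tsv",
        "detections": out / "detections.tsv",
        "homologs": out / "homologs.tsv",
        "planted": out / "planted.txt",
    }
    write_study_database(db.studies, db.layers, paths["studies"], paths["detections"])
    db.homologs.to_frame().to_csv(paths["homologs"], sep="\t", index=False)
    paths["planted"].write_text("\n".join(db.planted) + "\n")
    return paths


def generate_annotation(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[GeneAnnotation, pd.DataFrame, dict[str, Path]]:
    """Toy annotation: evenly spaced non-overlapping genes plus marker fixtures.

    Writes genes.gff3, chrom.sizes and markers.tsv; gene models never extend
    past their chromosome (the constructor refuses otherwise).
    """
    rng = np.random.default_rng(config.seed + 1)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chrom_lengths = {
        f"chr{c}": config.chrom_length_bp for c in range(1, config.n_chromosomes + 1)
    }
    records: list[tuple[str, GenomicInterval]] = []
    gff_lines = ["##gff-version 3"]
    for chrom, length in chrom_lengths.items():
        n = config.genes_per_chromosome
        if n == 0:
            continue
        spacing = length // max(n, 1)
        if config.gene_length_bp >= spacing:
            raise ValueError("gene length exceeds spacing; genes would overlap")
        for i in range(n):
            start = i * spacing + 1
            end = start + config.gene_length_bp - 1
            sym = f"{chrom.upper()}G{i + 1:03d}"
            records.append((sym, GenomicInterval(chrom, start, end)))
            gff_lines.append(
                f"{chrom}\tsynthetic\tgene\t{start}\t{end}\t.\t+\t.\tID={sym};Name={sym}"
            )
    annotation = GeneAnnotation(records, chrom_lengths)
    paths = {
        "gff3": out / "genes.gff3",
        "chrom_sizes": out / "chrom.sizes",
        "markers": out / "markers.tsv",
    }
    paths["gff3"].write_text("\n".join(gff_lines) + "\n")
    paths["chrom_sizes"].write_text(
        "".join(f"{c}\t{l}\n" for c, l in chrom_lengths.items())
    )
    # markers must reference studies that declare the matching evidence kind;
    # regenerate the (deterministic) study list to pick consistent ids
    db = generate_database(config)
    assoc_studies = sorted(
        s.study_id for s in db.studies if "association" in s.evidence_kinds
    )
    linkage_studies = sorted(
        s.study_id for s in db.studies if "linkage" in s.evidence_kinds
    )
    marker_rows = []
    for j, (chrom, length) in enumerate(chrom_lengths.items()):
        if assoc_studies:
            marker_rows.append(
                {
                    "study_id": assoc_studies[j % len(assoc_studies)],
                    "chromosome": chrom,
                    "position_bp": int(rng.integers(1, length + 1)),
                    "peak_cm": "",
                    "start_bp": "",
                    "end_bp": "",
                }
            )
        if linkage_studies:
            marker_rows.append(
                {
                    "study_id": linkage_studies[j % len(linkage_studies)],
                    "chromosome": chrom,
                    "position_bp": "",
                    "peak_cm": float(rng.uniform(0, length / 1_000_000)),
                    "start_bp": "",
                    "end_bp": "",
                }
            )
    markers = pd.DataFrame(
        marker_rows,
        columns=["study_id", "chromosome", "position_bp", "peak_cm", "start_bp", "end_bp"],
    )
    markers.to_csv(paths["markers"], sep="\t", index=False)
    return annotation, markers, paths


def generate_function_annotations(
    config: SyntheticConfig, out_dir: str | Path, n_sets: int = 20, set_size: int = 50
) -> dict[str, Path]:
    """Gene sets (GMT) and an interaction edge list for the enrichment stage.

    Half of the gene sets are seeded with planted molecules (true enrichment
    signal); the edge list wires the planted molecules densely and adds
    sparse background edges.
    """
    rng = np.random.default_rng(config.seed + 2)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    db_rng = np.random.default_rng(config.seed)
    universe = [f"G{i:04d}" for i in range(1, config.n_molecules + 1)]
    planted_idx = db_rng.choice(config.n_molecules, size=config.n_planted, replace=False)
    planted = [universe[i] for i in sorted(planted_idx)]

    lines = []
    for s in range(n_sets):
        members: set[str] = set()
        if s < n_sets // 2:
            members |= set(
                rng.choice(planted, size=min(len(planted), set_size // 5), replace=False)
            )
        members |= set(rng.choice(universe, size=set_size, replace=False))
        lines.append("\t".join([f"SET{s + 1:02d}", "function", *sorted(members)]))
    gmt_path = out / "sets.gmt"
    gmt_path.write_text("\n".join(lines) + "\n")

    edges: set[tuple[str, str]] = set()
    for i, a in enumerate(planted):
        for b in planted[i + 1 :]:
            if rng.random() < 0.3:
                edges.add(tuple(sorted((a, b))))
    n_background = 5 * config.n_planted
    pairs = rng.integers(0, config.n_molecules, size=(n_background, 2))
    for a_i, b_i in pairs:
        if a_i != b_i:
            edges.add(tuple(sorted((universe[a_i], universe[b_i]))))
    edges_path = out / "edges.tsv"
    edges_path.write_text("".join(f"{a}\t{b}\n" for a, b in sorted(edges)))
    return {"gene_sets": gmt_path, "edges": edges_path}


def recovery_experiment(
    config: SyntheticConfig, n_replicates: int
) -> dict:
    """Planted-signal recovery of the full CE pipeline.

    Per replicate (seed = config.seed + r): generate a database, run the
    prioritization end to end (homolog translation included), take the top
    K = n_planted ranked molecules and measure the fraction of planted
    molecules recovered, plus mean ranks of planted vs background molecules
    (a planted molecule absent from the ranking counts at rank = universe
    size). The report carries the mean, SD and a normal-approximation 95% CI
    across replicates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if config.p_signal <= config.p_noise:
        raise ValueError(
            "recovery requires p_signal > p_noise "
            f"(got {config.p_signal} <= {config.p_noise})"
        )
    fractions: list[float] = []
    planted_ranks: list[float] = []
    background_ranks: list[float] = []
    for r in range(n_replicates):
        cfg = dataclasses.replace(config, seed=config.seed + r)
        db = generate_database(cfg)
        result = prioritize(db.studies, db.layers, db.homologs)
        top = {res.molecule for res in result.ranking[: config.n_planted]}
        planted = set(db.planted)
        fractions.append(len(top & planted) / config.n_planted)
        rank_of = {res.molecule: res.rank for res in result.ranking}
        worst = len(db.universe)
        pr = [rank_of.get(m, worst) for m in planted]
        br = [res.rank for res in result.ranking if res.molecule not in planted]
        planted_ranks.append(float(np.mean(pr)))
        background_ranks.append(float(np.mean(br)) if br else float("nan"))
    mean = float(np.mean(fractions))
    sd = float(np.std(fractions, ddof=1)) if n_replicates > 1 else 0.0
    half = 1.96 * sd / math.sqrt(n_replicates) if n_replicates > 1 else 0.0
    return {
        "n_replicates": n_replicates,
        "n_planted": config.n_planted,
        "p_signal": config.p_signal,
        "p_noise": config.p_noise,
        "recovery_mean": mean,
        "recovery_sd": sd,
        "recovery_ci95": [max(0.0, mean - half), min(1.0, mean + half)],
        "mean_rank_planted": float(np.mean(planted_ranks)),
        "mean_rank_background": float(np.mean(background_ranks)),
        "per_replicate": fractions,
    }


def write_recovery_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
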