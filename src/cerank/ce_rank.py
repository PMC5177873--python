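"""Convergent-evidence scoring, ranking and top-quantile selection.

The CE score of molecule g over a set of evidence layers is the weighted
arithmetic mean of its binary detection indicators:

    CE_g = sum_i w_i * e_gi / sum_i w_i

where w_i is layer i's custom score and e_gi is 1 when layer i detected g.
Molecules are ranked by score (ties broken by raw detection count, then
identifier), and the candidate set is the top ceil((1 - q) * N) of the
ranking; q defaults to 0.995. The same machinery reruns within each
subphenotype class using only that class's layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evidence_model import (
    DetectionMatrix,
    EvidenceLayer,
    PHENOTYPE_CLASSES,
    Study,
)

DEFAULT_QUANTILE = 0.995


@dataclass
class CEResult:
    """Per-molecule convergent-evidence result."""

    molecule: str
    score: float
    rank: int
    n_layers_detected: int
    species_counts: dict[str, int] = field(default_factory=dict)
    class_counts: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class QuantileRule:
    """Top-quantile selection: keep the highest-ranked ceil((1-q)*N)."""

    q: float = DEFAULT_QUANTILE

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"quantile q must lie in (0, 1), got {self.q}")

    def selected_count(self, n: int) -> int:
        # tolerate float noise in (1-q)*n so exact fractions don't round up
        return max(1, math.ceil((1.0 - self.q) * n - 1e-9))


def ce_scores(
    matrix: DetectionMatrix, weights: Mapping[str, float]
) -> pd.Series:
    """Weighted mean of detection indicators per molecule.

    Vectorized as w @ E / sum(w) over the layer axis.
    """
    missing = [l for l in matrix.layers if l not in weights]
    if missing:
        raise KeyError(f"no weight for layers {missing[:5]}")
    w = np.asarray([weights[l] for l in matrix.layers], dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("total layer weight must be positive")
    scores = w @ matrix.values.astype(float) / total
    return pd.Series(scores, index=matrix.molecules, name="ce_score")


def rank_molecules(
    scores: Mapping[str, float] | pd.Series,
    detection_counts: Mapping[str, int] | None = None,
    species_counts: Mapping[str, Mapping[str, int]] | None = None,
    class_counts: Mapping[str, Mapping[str, int]] | None = None,
) -> list[CEResult]:
    """Deterministic ranking: score desc, detection count desc, identifier asc."""
    if isinstance(scores, pd.Series):
        scores = scores.to_dict()
    if not scores:
        raise ValueError("cannot rank an empty score map")
    counts = dict(detection_counts or {})
    order = sorted(
        scores.items(), key=lambda kv: (-kv[1], -counts.get(kv[0], 0), kv[0])
    )
    results = []
    for rank, (mol, score) in enumerate(order, start=1):
        results.append(
            CEResult(
                molecule=mol,
                score=float(score),
                rank=rank,
                n_layers_detected=counts.get(mol, 0),
                species_counts=dict((species_counts or {}).get(mol, {})),
                class_counts=dict((class_counts or {}).get(mol, {})),
            )
        )
    return results


def select_top_quantile(
    ranked: Sequence[CEResult], q: float = DEFAULT_QUANTILE
) -> list[CEResult]:
    """First ceil((1-q)*N) molecules of the ranking (q=0.995: 7895 -> 40)."""
    rule = QuantileRule(q)
    return list(ranked[: rule.selected_count(len(ranked))])


def _study_counts(
    matrix: DetectionMatrix,
    studies: Sequence[Study],
    layers: Sequence[EvidenceLayer],
) -> tuple[dict[str, dict[str, int]], dict[str, dict[str, int]]]:
    """Per-molecule counts of distinct detecting studies, by species and class."""
    by_id = {s.study_id: s for s in studies}
    layer_study = {l.layer_id: l.study_id for l in layers}
    species_counts: dict[str, dict[str, int]] = {}
    class_counts: dict[str, dict[str, int]] = {}
    frame = matrix.data
    for mol in frame.columns:
        detecting_layers = frame.index[frame[mol] == 1]
        study_ids = {layer_study[l] for l in detecting_layers}
        sp: dict[str, int] = {}
        cl: dict[str, int] = {}
        for sid in study_ids:
            study = by_id[sid]
            sp[study.species_group] = sp.get(study.species_group, 0) + 1
            for c in study.phenotype_classes:
                cl[c] = cl.get(c, 0) + 1
        species_counts[mol] = sp
        class_counts[mol] = cl
    return species_counts, class_counts


def rank_from_matrix(
    matrix: DetectionMatrix,
    weights: Mapping[str, float],
    studies: Sequence[Study] | None = None,
    layers: Sequence[EvidenceLayer] | None = None,
) -> list[CEResult]:
    """Score + rank in one step, with study counts when metadata is given."""
    scores = ce_scores(matrix, weights)
    counts = matrix.detection_counts().to_dict()
    species_counts = class_counts = None
    if studies is not None and layers is not None:
        species_counts, class_counts = _study_counts(matrix, studies, layers)
    return rank_molecules(scores, counts, species_counts, class_counts)


def stratified_rank(
    studies: Sequence[Study],
    layers: Sequence[EvidenceLayer],
    matrix: DetectionMatrix,
    weights: Mapping[str, float],
    phenotype_class: str,
) -> list[CEResult]:
    """Rerun CE scoring within one subphenotype class.

    Only layers whose parent study carries the class contribute; the weight
    denominator is recomputed over that subset, and molecules undetected in
    the subset are excluded from its ranking. Scores are therefore
    comparable within, not across, strata.
    """
    if phenotype_class not in PHENOTYPE_CLASSES:
        raise ValueError(f"unknown phenotype class {phenotype_class!r}")
    by_id = {s.study_id: s for s in studies}
    keep = [
        l.layer_id
        for l in layers
        if phenotype_class in by_id[l.study_id].phenotype_classes
    ]
    if not keep:
        raise ValueError(f"no layers in phenotype class {phenotype_class!r}")
    sub = matrix.data.loc[keep]
    sub = sub.loc[:, sub.sum(axis=0) > 0]
    sub_matrix = DetectionMatrix(sub)
    sub_layers = [l for l in layers if l.layer_id in set(keep)]
    return rank_from_matrix(sub_matrix, weights, studies, sub_layers)


def results_frame(results: Sequence[CEResult], decimals: int = 3) -> pd.DataFrame:
    """Ranking table (scores rounded only here, at reporting time)."""
    species_keys = ["human", "songbird", "other_animal"]
    rows = []
    for r in results:
        row = {
            "rank": r.rank,
            "molecule": r.molecule,
            "score": round(r.score, decimals),
            "n_layers_detected": r.n_layers_detected,
        }
        for sp in species_keys:
            row[f"n_studies_{sp}"] = r.species_counts.get(sp, 0)
        for c in PHENOTYPE_CLASSES:
            row[f"n_studies_{c}"] = r.class_counts.get(c, 0)
        rows.append(row)
    return pd.DataFrame(rows)
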