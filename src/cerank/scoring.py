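"""Custom scores: the per-layer weight w_i used by the convergent-evidence mean.

Each evidence layer's weight is the product of three self-importance factors,
each ranging from 0.8 (penalized) to 1.0 (full confidence):

* phenotype factor — 1.0 when the study measured a musical trait precisely,
  0.8 for related phenotypes;
* homology factor — 1.0 for human studies, 0.8 for other species (homolog
  conversion may introduce errors);
* sample-size factor — linear from 0.8 (smallest study) to 1.0 (largest),
  scaled separately within the gene-mapping and the other-studies pools;

times a 0.9 multiplier applied to a linkage layer whose study also
contributed an association layer. Weights therefore span [0.8^3 * 0.9, 1];
without the linkage penalty the range is [0.512, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .evidence_model import EvidenceLayer, Study

logger = logging.getLogger(__name__)

FACTOR_FLOOR = 0.8
FACTOR_CEIL = 1.0
LINKAGE_MULTIPLIER = 0.9

MIN_WEIGHT_NO_PENALTY = FACTOR_FLOOR**3          # 0.512
MIN_WEIGHT = MIN_WEIGHT_NO_PENALTY * LINKAGE_MULTIPLIER  # 0.4608


@dataclass(frozen=True)
class WeightComponents:
    """Audit record of a layer weight's factor decomposition."""

    phenotype_factor: float
    homology_factor: float
    size_factor: float
    linkage_multiplier: float

    @property
    def weight(self) -> float:
        return (
            self.phenotype_factor
            * self.homology_factor
            * self.size_factor
            * self.linkage_multiplier
        )

    def __post_init__(self) -> None:
        if self.phenotype_factor not in (FACTOR_FLOOR, FACTOR_CEIL):
            raise ValueError(f"phenotype_factor must be 0.8 or 1.0, got {self.phenotype_factor}")
        if self.homology_factor not in (FACTOR_FLOOR, FACTOR_CEIL):
            raise ValueError(f"homology_factor must be 0.8 or 1.0, got {self.homology_factor}")
        if not FACTOR_FLOOR <= self.size_factor <= FACTOR_CEIL:
            raise ValueError(f"size_factor must lie in [0.8, 1], got {self.size_factor}")
        if self.linkage_multiplier not in (LINKAGE_MULTIPLIER, 1.0):
            raise ValueError(
                f"linkage_multiplier must be 0.9 or 1.0, got {self.linkage_multiplier}"
            )


def size_scores(
    sample_sizes: Mapping[str, int | None], group_label: str = ""
) -> dict[str, float]:
    """Linear sample-size factors for one scaling pool of studies.

    The smallest study scores 0.8 and the largest 1.0, linear in between.
    A pool with a single size (or all sizes equal) scores 1.0. Missing sizes
    take the floor 0.8 with a warning.
    """
    present = {sid: s for sid, s in sample_sizes.items() if s is not None}
    for sid, size in present.items():
        if size <= 0:
            raise ValueError(f"study {sid!r}: non-positive sample size {size}")
    factors: dict[str, float] = {}
    if present:
        lo, hi = min(present.values()), max(present.values())
        for sid, size in present.items():
            if lo == hi:
                factors[sid] = FACTOR_CEIL
            else:
                factors[sid] = FACTOR_FLOOR + (FACTOR_CEIL - FACTOR_FLOOR) * (
                    size - lo
                ) / (hi - lo)
    for sid, size in sample_sizes.items():
        if size is None:
            logger.warning(
                "study %r has no sample size; size factor set to the floor %.1f%s",
                sid,
                FACTOR_FLOOR,
                f" (pool {group_label})" if group_label else "",
            )
            factors[sid] = FACTOR_FLOOR
    return factors


def layer_weight(
    study: Study,
    layer_kind: str,
    size_factor: float,
    has_paired_association: bool,
) -> WeightComponents:
    """Combine the three factors and the linkage penalty for one layer."""
    if not FACTOR_FLOOR <= size_factor <= FACTOR_CEIL:
        raise ValueError(f"size_factor must lie in [0.8, 1], got {size_factor}")
    return WeightComponents(
        phenotype_factor=FACTOR_CEIL if study.phenotype_precise else FACTOR_FLOOR,
        homology_factor=FACTOR_CEIL if study.species_group == "human" else FACTOR_FLOOR,
        size_factor=size_factor,
        linkage_multiplier=(
            LINKAGE_MULTIPLIER
            if layer_kind == "linkage" and has_paired_association
            else 1.0
        ),
    )


def score_all_layers(
    studies: Sequence[Study], layers: Sequence[EvidenceLayer]
) -> tuple[list[EvidenceLayer], dict[str, WeightComponents]]:
    """Attach a weight to every layer; returns weighted layers + audit records.

    Sample-size scaling pools follow Study.study_group (gene_mapping vs
    other); the linkage penalty applies to a linkage layer whenever the same
    study also contributed at least one association layer.
    """
    by_id = {s.study_id: s for s in studies}
    for layer in layers:
        if layer.study_id not in by_id:
            raise ValueError(f"layer {layer.layer_id!r} references unknown study")
    size_factors: dict[str, float] = {}
    for group in sorted({s.study_group for s in studies}):
        pool = {s.study_id: s.sample_size for s in studies if s.study_group == group}
        size_factors.update(size_scores(pool, group_label=group))
    assoc_studies = {l.study_id for l in layers if l.layer_kind == "association"}
    weighted: list[EvidenceLayer] = []
    components: dict[str, WeightComponents] = {}
    for layer in layers:
        study = by_id[layer.study_id]
        comp = layer_weight(
            study,
            layer.layer_kind,
            size_factors[study.study_id],
            has_paired_association=layer.study_id in assoc_studies,
        )
        components[layer.layer_id] = comp
        weighted.append(replace(layer, weight=comp.weight))
    return weighted, components


def weights_frame(components: Mapping[str, WeightComponents]):
    """Audit table mirroring the weights.tsv output schema."""
    import pandas as pd

    rows = [
        {
            "layer_id": layer_id,
            "phenotype_factor": c.phenotype_factor,
            "homology_factor": c.homology_factor,
            "size_factor": c.size_factor,
            "linkage_multiplier": c.linkage_multiplier,
            "weight": c.weight,
        }
        for layer_id, c in sorted(components.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "layer_id",
            "phenotype_factor",
            "homology_factor",
            "size_factor",
            "linkage_multiplier",
            "weight",
        ],
    )
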