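"""Region-to-gene mapping for association markers and linkage peaks.

Association markers become +/-500 kb windows; linkage peaks reported only in
genetic map units are converted to physical coordinates at 1 cM = 1 Mb.
Genes overlapping the resulting interval by at least one base pair are
extracted from the annotation. All coordinates are 1-based inclusive
(GFF3/Ensembl convention); BED input is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

CM_TO_BP = 1_000_000  # 1 cM = 1 Mb
DEFAULT_FLANK_BP = 500_000
DEFAULT_LINKAGE_HALF_WIDTH_CM = 10.0


@dataclass(frozen=True)
class GenomicInterval:
    """Closed interval [start, end] on a chromosome, 1-based inclusive."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError("chromosome must be non-empty")
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}] on {self.chromosome}"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )

    @property
    def width(self) -> int:
        return self.end - self.start + 1


class GeneAnnotation:
    """Gene records indexed by chromosome for fast interval queries."""

    def __init__(
        self,
        records: Sequence[tuple[str, GenomicInterval]],
        chrom_lengths: Mapping[str, int],
    ) -> None:
        symbols = [sym for sym, _ in records]
        if len(symbols) != len(set(symbols)):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate gene symbols in annotation: {dupes[:5]}")
        for sym, iv in records:
            length = chrom_lengths.get(iv.chromosome)
            if length is not None and iv.end > length:
                raise ValueError(
                    f"gene {sym!r} extends past the end of {iv.chromosome} "
                    f"({iv.end} > {length})"
                )
        self.records = list(records)
        self.chrom_lengths = dict(chrom_lengths)
        self._trees: dict[str, IntervalTree] = {}
        for sym, iv in records:
            tree = self._trees.setdefault(iv.chromosome, IntervalTree())
            # intervaltree is half-open; store [start, end+1)
            tree.addi(iv.start, iv.end + 1, (sym, iv))

    @staticmethod
    def read_chrom_sizes(path: str | Path) -> dict[str, int]:
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))

    @classmethod
    def from_gff3(cls, path: str | Path, chrom_lengths: Mapping[str, int]) -> "GeneAnnotation":
        """Read gene-type features; symbol from the Name/gene_name attribute."""
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
        )
        records = []
        for feat in db.features_of_type("gene"):
            attrs = feat.attributes
            names = attrs.get("Name") or attrs.get("gene_name") or attrs.get("ID")
            if not names:
                raise ValueError(f"gene feature at {feat.seqid}:{feat.start} has no Name")
            records.append(
                (names[0], GenomicInterval(str(feat.seqid), int(feat.start), int(feat.end)))
            )
        return cls(records, chrom_lengths)

    @classmethod
    def from_bed(cls, path: str | Path, chrom_lengths: Mapping[str, int]) -> "GeneAnnotation":
        """Read BED (0-based half-open); converted to 1-based inclusive."""
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "name"],
        )
        records = [
            (str(name), GenomicInterval(str(chrom), int(start) + 1, int(end)))
            for chrom, start, end, name in zip(
                df["chrom"], df["start"], df["end"], df["name"]
            )
        ]
        return cls(records, chrom_lengths)


def _clamp(start: float, end: float, chrom: str, chrom_lengths: Mapping[str, int]) -> GenomicInterval:
    if chrom not in chrom_lengths:
        raise KeyError(f"unknown chromosome {chrom!r}")
    length = chrom_lengths[chrom]
    return GenomicInterval(
        chrom, max(1, int(round(start))), min(length, int(round(end)))
    )


def association_window(
    marker: tuple[str, int],
    flank: int = DEFAULT_FLANK_BP,
    chrom_lengths: Mapping[str, int] | None = None,
) -> GenomicInterval:
    """+/-`flank` bp window around an associated marker, clamped to the chromosome."""
    chrom, position = marker
    if position < 1:
        raise ValueError(f"marker position must be >= 1, got {position}")
    if chrom_lengths is None:
        raise KeyError("chromosome length table required")
    return _clamp(position - flank, position + flank, chrom, chrom_lengths)


def linkage_interval_from_cm(
    peak_cm: float,
    half_width_cm: float,
    chrom: str,
    chrom_lengths: Mapping[str, int],
) -> GenomicInterval:
    """Physical interval around a linkage peak reported in centimorgans.

    The genetic-to-physical conversion is exactly 1 cM = 1 Mb.
    """
    if peak_cm < 0:
        raise ValueError(f"peak_cm must be >= 0, got {peak_cm}")
    if half_width_cm <= 0:
        raise ValueError(f"half_width_cm must be > 0, got {half_width_cm}")
    start = (peak_cm - half_width_cm) * CM_TO_BP
    end = (peak_cm + half_width_cm) * CM_TO_BP
    return _clamp(start, end, chrom, chrom_lengths)


def genes_in_interval(region: GenomicInterval, annotation: GeneAnnotation) -> list[str]:
    """Symbols of genes overlapping `region` by >=1 bp, sorted by start then symbol.

    Returns an empty list (not an error) for gene deserts; the caller drops
    the marker and logs it.
    """
    tree = annotation._trees.get(region.chromosome)
    if tree is None:
        return []
    hits = tree.overlap(region.start, region.end + 1)
    ordered = sorted((iv.data[1].start, iv.data[0]) for iv in hits)
    return [sym for _, sym in ordered]


def read_markers(path: str | Path) -> pd.DataFrame:
    """Read the markers table (association positions and/or linkage peaks/regions)."""
    df = pd.read_csv(path, sep="\t", dtype={"study_id": str, "chromosome": str})
    required = {"study_id", "chromosome"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"markers table missing columns {sorted(missing)}")
    return df


def marker_detections(
    markers: pd.DataFrame,
    annotation: GeneAnnotation,
    flank: int = DEFAULT_FLANK_BP,
    half_width_cm: float = DEFAULT_LINKAGE_HALF_WIDTH_CM,
) -> tuple[pd.DataFrame, list[dict]]:
    """Convert marker rows into gene detection rows.

    Rows with `position_bp` are treated as association markers (+/-flank
    window); rows with `start_bp`/`end_bp` as explicit linkage regions; rows
    with only `peak_cm` as linkage peaks converted at 1 cM = 1 Mb. Markers
    whose window contains no gene are dropped and reported.
    """
    rows: list[dict] = []
    dropped: list[dict] = []
    for rec in markers.to_dict("records"):
        chrom = str(rec["chromosome"])
        if pd.notna(rec.get("position_bp")):
            kind = "association"
            region = association_window(
                (chrom, int(rec["position_bp"])), flank, annotation.chrom_lengths
            )
        elif pd.notna(rec.get("start_bp")) and pd.notna(rec.get("end_bp")):
            kind = "linkage"
            region = _clamp(
                int(rec["start_bp"]), int(rec["end_bp"]), chrom, annotation.chrom_lengths
            )
        elif pd.notna(rec.get("peak_cm")):
            kind = "linkage"
            region = linkage_interval_from_cm(
                float(rec["peak_cm"]), half_width_cm, chrom, annotation.chrom_lengths
            )
        else:
            raise ValueError(f"marker row for study {rec['study_id']!r} has no coordinates")
        genes = genes_in_interval(region, annotation)
        if not genes:
            logger.warning(
                "marker %s:%s (study %s) dropped: no genes within boundaries",
                region.chromosome,
                region.start,
                rec["study_id"],
            )
            dropped.append({"study_id": rec["study_id"], "region": region})
            continue
        for gene in genes:
            rows.append(
                {
                    "study_id": rec["study_id"],
                    "evidence_kind": kind,
                    "dataset_id": "1",
                    "molecule": gene,
                }
            )
    return pd.DataFrame(rows, columns=["study_id", "evidence_kind", "dataset_id", "molecule"]), dropped
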