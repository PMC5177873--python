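"""Cross-species translation of detected molecules to human gene symbols.

Homology is supplied as a many-to-many table (species, source identifier,
human symbol). A non-human gene with several human homologs expands to all
of them; identifiers without a mapping are dropped and counted. Human
identifiers pass through unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

HUMAN = "human"


@dataclass
class UnmappedReport:
    """Identifiers that found no human homolog in the table."""

    n_input: int
    unmapped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_unmapped(self) -> int:
        return len(self.unmapped)

    @property
    def fraction_unmapped(self) -> float:
        return self.n_unmapped / self.n_input if self.n_input else 0.0


class HomologTable:
    """Many-to-many (species, source_id) -> human symbol mapping."""

    def __init__(self, triples: Iterable[tuple[str, str, str]] = ()) -> None:
        self._map: dict[tuple[str, str], set[str]] = {}
        for species, source_id, human_symbol in triples:
            key = (str(species), str(source_id))
            self._map.setdefault(key, set()).add(str(human_symbol).strip().upper())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HomologTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"species", "source_id", "human_symbol"} - set(df.columns)
        if missing:
            raise ValueError(f"homolog table missing columns {sorted(missing)}")
        return cls(df[["species", "source_id", "human_symbol"]].itertuples(index=False))

    def lookup(self, species: str, identifier: str) -> list[str]:
        return sorted(self._map.get((species, identifier), ()))

    def __len__(self) -> int:
        return sum(len(v) for v in self._map.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species": sp, "source_id": src, "human_symbol": hs}
            for (sp, src), symbols in sorted(self._map.items())
            for hs in sorted(symbols)
        ]
        return pd.DataFrame(rows, columns=["species", "source_id", "human_symbol"])


def translate_to_human(
    detected: Sequence[tuple[str, str]],
    table: HomologTable,
    passthrough: Iterable[str] = (),
) -> tuple[list[str], UnmappedReport]:
    """Expand (species, identifier) pairs into human symbols.

    Human inputs pass through unchanged (upper-cased); each non-human
    identifier expands to *all* of its human homologs; unmapped identifiers
    are dropped and reported. Identifiers in `passthrough` (e.g. the
    biomarker vocabulary, matched case-insensitively) skip translation for
    any species. Output is deduplicated, preserving first-seen order.
    """
    passthrough_lc = {p.lower() for p in passthrough}
    if len(table) == 0 and any(sp != HUMAN for sp, ident in detected
                               if ident.lower() not in passthrough_lc):
        logger.warning("empty homolog table with non-human input: all unmapped")
    out: list[str] = []
    seen: set[str] = set()
    report = UnmappedReport(n_input=len(detected))

    def emit(symbol: str) -> None:
        if symbol not in seen:
            seen.add(symbol)
            out.append(symbol)

    for species, ident in detected:
        if species == HUMAN or ident.lower() in passthrough_lc:
            emit(ident.strip().upper() if ident.lower() not in passthrough_lc else ident)
            continue
        homologs = table.lookup(species, ident)
        if not homologs:
            report.unmapped.append((species, ident))
            continue
        for symbol in homologs:
            emit(symbol)
    return out, report
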