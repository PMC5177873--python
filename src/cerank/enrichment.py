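"""Functional characterization of the top candidate set.

Over-representation of the top molecules in user-supplied gene sets is
tested with the one-sided Fisher exact (hypergeometric upper-tail) test.
Interaction subnetworks are grown greedily from triangle-count seeds: the
focus molecule sitting in the most triangles seeds a network, which then
adds the candidate with most edges into the current network (focus
molecules preferred) until a size cap — 35 nodes by default — is reached or
nothing connects; successive networks are node-disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

DEFAULT_MAX_NETWORK_SIZE = 35


@dataclass
class GeneSet:
    name: str
    members: frozenset[str]
    category: str = "function"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass
class EnrichmentResult:
    """One gene set's over-representation statistics (2x2 table + tail p)."""

    name: str
    category: str
    overlap: int        # k: top-set members inside the set
    set_size: int       # m: set members inside the universe
    top_size: int       # n: size of the top set
    universe_size: int  # N
    p_value: float
    adjusted_p: float | None = None


@dataclass
class InteractionNetwork:
    network_id: int
    nodes: list[str]
    focus_nodes: list[str]
    edges: list[tuple[str, str]]

    @property
    def n_focus(self) -> int:
        return len(self.focus_nodes)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """One gene set per line: name <tab> description <tab> members..."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets.append(
                GeneSet(
                    name=parts[0],
                    members=frozenset(p for p in parts[2:] if p),
                    category=parts[1] or "function",
                )
            )
    return sets


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV (or three-column SIF) of undirected interactions."""
    edges = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 3:  # SIF: node relation node
                a, b = parts[0], parts[2]
            elif len(parts) >= 2:
                a, b = parts[0], parts[1]
            else:
                continue
            if a and b and a != b:
                edges.append((a, b))
    return edges


def fisher_enrichment(
    top_set: Iterable[str],
    gene_sets: Sequence[GeneSet],
    universe: Iterable[str],
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """One-sided over-representation p-value per gene set.

    p = P(X >= k) for X ~ Hypergeom(N, m, n) with N the universe size, m the
    gene set's size within the universe, n the top-set size and k the
    overlap. Gene-set members outside the universe are ignored. Results are
    sorted by p ascending (ties by name); Benjamini-Hochberg adjustment is
    optional and off by default.
    """
    universe = set(universe)
    top = set(top_set)
    if not universe:
        raise ValueError("universe must be non-empty")
    if not top:
        raise ValueError("top set must be non-empty")
    if not top <= universe:
        raise ValueError("top set must be a subset of the universe")
    N, n = len(universe), len(top)
    results = []
    for gs in gene_sets:
        members = gs.members & universe
        m = len(members)
        k = len(members & top)
        # upper tail P(X >= k); sf(k-1) includes k itself
        p = float(hypergeom.sf(k - 1, N, m, n)) if m else 1.0
        results.append(
            EnrichmentResult(
                name=gs.name,
                category=gs.category,
                overlap=k,
                set_size=m,
                top_size=n,
                universe_size=N,
                p_value=min(p, 1.0),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.name))
    if adjust and results:
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "name": r.name,
            "category": r.category,
            "overlap": r.overlap,
            "set_size": r.set_size,
            "top_size": r.top_size,
            "universe_size": r.universe_size,
            "p_value": r.p_value,
            **({"adjusted_p": r.adjusted_p} if r.adjusted_p is not None else {}),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def _pick_seed(graph: nx.Graph, focus_present: set[str]) -> str:
    """Most triangle-embedded focus molecule; ties by degree, then name."""
    triangles = nx.triangles(graph)
    return min(
        focus_present,
        key=lambda v: (-triangles.get(v, 0), -graph.degree(v), v),
    )


def build_networks(
    focus: Sequence[str],
    edges: Sequence[tuple[str, str]],
    max_size: int = DEFAULT_MAX_NETWORK_SIZE,
) -> list[InteractionNetwork]:
    """Grow node-disjoint interaction subnetworks around triangle-count seeds.

    Each round seeds on the remaining focus molecule participating in the
    most triangles (ties: degree, then name) and grows by repeatedly adding
    the neighbour with the most edges into the current network, preferring
    focus molecules, until `max_size` nodes or no candidate connects. Nodes
    used by one network are removed before the next is seeded; focus
    molecules left with no interactions do not form singleton networks.
    """
    if not focus:
        raise ValueError("focus list must be non-empty")
    if max_size < 2:
        raise ValueError(f"max_size must be >= 2, got {max_size}")
    graph = nx.Graph()
    graph.add_edges_from((a, b) for a, b in edges if a != b)
    if graph.number_of_edges() == 0:
        logger.warning("empty edge list: no networks built")
        return []
    focus_set = set(focus)
    remaining = graph.copy()
    networks: list[InteractionNetwork] = []
    while True:
        focus_present = {
            v for v in focus_set if v in remaining and remaining.degree(v) > 0
        }
        if not focus_present:
            break
        seed = _pick_seed(remaining, focus_present)
        nodes = [seed]
        node_set = {seed}
        while len(nodes) < max_size:
            candidates: dict[str, int] = {}
            for v in node_set:
                for nb in remaining.neighbors(v):
                    if nb not in node_set:
                        candidates[nb] = candidates.get(nb, 0) + 1
            if not candidates:
                break
            best = min(
                candidates,
                key=lambda v: (-candidates[v], v not in focus_set, v),
            )
            nodes.append(best)
            node_set.add(best)
        net_edges = sorted(
            tuple(sorted(e)) for e in remaining.subgraph(node_set).edges()
        )
        networks.append(
            InteractionNetwork(
                network_id=len(networks) + 1,
                nodes=nodes,
                focus_nodes=[v for v in nodes if v in focus_set],
                edges=net_edges,
            )
        )
        remaining.remove_nodes_from(node_set)
    return networks


def networks_frame(networks: Sequence[InteractionNetwork]) -> pd.DataFrame:
    rows = [
        {"network_id": net.network_id, "node": node, "is_focus": int(node in set(net.focus_nodes))}
        for net in networks
        for node in net.nodes
    ]
    return pd.DataFrame(rows, columns=["network_id", "node", "is_focus"])
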