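"""Assembly of the confidence-filtered interaction network.

Interaction evidence arrives as a 4-column edge list (geneA, geneB,
confidence in [0,1], evidence type).  Edges below the confidence cutoff
(default 0.70, the boundary value itself retained) are rejected, and the
analysis network is assembled around the union of the seed gene modules —
either the induced subgraph on the seeds alone or, by default, seeds plus
their first neighbors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .ranking import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionEdge",
    "read_edges",
    "parse_edge_lines",
    "write_edges",
    "filter_by_confidence",
    "assemble",
    "write_sif",
    "read_sif",
    "write_graphml",
]

EVIDENCE_TYPES = frozenset({"physical", "genetic", "text_mined", "unknown"})


@dataclass(frozen=True)
class InteractionEdge:
    """One undirected, confidence-scored interaction."""

    gene_a: str
    gene_b: str
    confidence: float
    evidence: str = "unknown"

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-loop on {self.gene_a!r}")

    @property
    def key(self) -> tuple[str, str]:
        """Canonical undirected key: the sorted endpoint pair."""
        return (self.gene_a, self.gene_b) if self.gene_a <= self.gene_b else (
            self.gene_b,
            self.gene_a,
        )


def parse_edge_lines(lines) -> tuple[list[InteractionEdge], int]:
    """Parse tab-separated edge lines; return (edges, malformed-line count).

    A line is malformed if it has fewer than 3 columns, a non-numeric or
    out-of-range confidence, or identical endpoints.  Identifier case is
    preserved; surrounding whitespace is trimmed; input order is kept.
    Duplicate pairs are NOT merged here — deduplication happens in
    :func:`assemble`.
    """
    edges: list[InteractionEdge] = []
    malformed = 0
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 3:
            malformed += 1
            continue
        a, b, conf_s = parts[0], parts[1], parts[2]
        evidence = parts[3] if len(parts) > 3 and parts[3] else "unknown"
        if evidence not in EVIDENCE_TYPES:
            evidence = "unknown"
        try:
            conf = float(conf_s)
        except ValueError:
            malformed += 1
            continue
        if not (0.0 <= conf <= 1.0) or not a or not b or a == b:
            malformed += 1
            continue
        edges.append(InteractionEdge(a, b, conf, evidence))
    return edges, malformed


def read_edges(path) -> list[InteractionEdge]:
    """Read a 4-column tab-separated edge list, reporting malformed lines."""
    with open(path) as fh:
        edges, malformed = parse_edge_lines(fh)
    if malformed:
        logger.warning("%s: %d malformed line(s) skipped", path, malformed)
    if not edges:
        raise ValueError(f"{path}: no valid interaction lines")
    return edges


def write_edges(edges: list[InteractionEdge], path) -> None:
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.confidence:.6g}\t{e.evidence}\n")


def filter_by_confidence(
    edges: list[InteractionEdge], threshold: float = 0.7
) -> list[InteractionEdge]:
    """Keep exactly the edges with confidence >= threshold, order preserved.

    The boundary value is retained: an edge scored exactly at the cutoff
    counts as trusted.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    return [e for e in edges if e.confidence >= threshold]


def _dedup_graph(edges: list[InteractionEdge], name: str) -> nx.Graph:
    """Undirected graph with duplicates merged, max confidence kept."""
    g = nx.Graph(name=name)
    for e in edges:
        a, b = e.key
        if g.has_edge(a, b):
            if e.confidence > g[a][b]["confidence"]:
                g[a][b]["confidence"] = e.confidence
                g[a][b]["evidence"] = e.evidence
        else:
            g.add_edge(a, b, confidence=e.confidence, evidence=e.evidence)
    return g


def assemble(
    seed_sets: list[GeneSet],
    edges: list[InteractionEdge],
    expansion: str = "first_neighbors",
    name: str = "network",
) -> nx.Graph:
    """Build the analysis network around the union of the seed gene sets.

    ``seeds_only`` keeps the induced subgraph on the seed union;
    ``first_neighbors`` additionally pulls in every node sharing an edge
    with a seed, plus all edges among included nodes.  Self-loops are
    impossible by edge construction; duplicate undirected edges are merged
    keeping the maximum confidence.  Seeds with no retained edge remain as
    isolated nodes.
    """
    seeds = set()
    for gs in seed_sets:
        seeds |= gs.members
    if not seeds:
        raise ValueError("union of seed sets is empty")

    full = _dedup_graph(edges, name)
    if expansion == "seeds_only":
        nodes = seeds
    elif expansion == "first_neighbors":
        nodes = set(seeds)
        for s in seeds & set(full.nodes):
            nodes.update(full.neighbors(s))
    else:
        raise ValueError(f"unknown expansion mode {expansion!r}")

    net = nx.Graph(full.subgraph(nodes & set(full.nodes)))
    net.add_nodes_from(seeds)  # isolated seeds retained
    net.graph["name"] = name
    for s in seeds:
        net.nodes[s]["seed"] = True
    logger.info(
        "%s: %d nodes, %d edges (expansion=%s, %d seeds)",
        name, net.number_of_nodes(), net.number_of_edges(), expansion, len(seeds),
    )
    return net


def edges_of(net: nx.Graph) -> list[InteractionEdge]:
    """Export a network back to an edge list (for idempotence / round-trips)."""
    return [
        InteractionEdge(a, b, d.get("confidence", 1.0), d.get("evidence", "unknown"))
        for a, b, d in net.edges(data=True)
    ]


def write_sif(net: nx.Graph, path, relation: str = "interacts") -> None:
    """Simple interaction format: 'A interacts B', isolated nodes bare."""
    with open(path, "w") as fh:
        for a, b in net.edges():
            fh.write(f"{a}\t{relation}\t{b}\n")
        for v in net.nodes():
            if net.degree(v) == 0:
                fh.write(f"{v}\n")


def read_sif(path, name: str = "sif") -> nx.Graph:
    g = nx.Graph(name=name)
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                g.add_edge(parts[0], parts[2], confidence=1.0, evidence="unknown")
            elif parts[0].strip():
                g.add_node(parts[0])
    return g


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)
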