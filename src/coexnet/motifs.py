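"""Dense-complex ("motif") detection, MCODE-style.

Each vertex is weighted by the highest k-core of its open neighborhood
(core number times that core's density); complexes grow outward from the
heaviest unvisited seed, admitting neighbors whose weight stays within a
fraction (the vertex weight percentage, VWP) of the seed's weight.  A
haircut prunes loosely attached members, complexes below 3 members are
discarded, and the survivors are scored by density x size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["Motif", "vertex_weights", "find_complexes", "top_motifs",
           "write_motif_table"]

MIN_COMPLEX_SIZE = 3


@dataclass(frozen=True)
class Motif:
    """A detected dense complex."""

    member_nodes: frozenset
    seed_node: str
    density: float
    score: float
    rank: int = 0

    def __len__(self) -> int:
        return len(self.member_nodes)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def vertex_weights(net: nx.Graph) -> dict:
    """k-core weight of every vertex.

    For vertex v, take the subgraph induced on v's neighbors (v itself
    excluded), find its highest k-core, and set
    weight(v) = k * density(that k-core).  Vertices with fewer than two
    neighbors — whose neighbor graph cannot contain an edge — get weight 0.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    weights = {}
    for v in net.nodes:
        nbrs = list(net.neighbors(v))
        if len(nbrs) < 2:
            weights[v] = 0.0
            continue
        g_n = net.subgraph(nbrs)
        if g_n.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core_num = nx.core_number(g_n)
        k = max(core_num.values())
        k_core = g_n.subgraph([u for u, c in core_num.items() if c >= k])
        weights[v] = k * _density(k_core)
    return weights


def _haircut(net: nx.Graph, members: set, seed: str) -> set:
    """Iteratively strip members with < 2 intra-complex connections (the
    2-core of the complex), then keep the component containing the seed so
    the complex stays internally connected."""
    sub = nx.Graph(net.subgraph(members))
    core = nx.k_core(sub, 2)
    if core.number_of_nodes() == 0:
        return set()
    comps = list(nx.connected_components(core))
    for comp in comps:
        if seed in comp:
            return set(comp)
    return set(max(comps, key=lambda c: (len(c), sorted(c)[0])))


def _fluff(net: nx.Graph, members: set, visited: set, fluff_density: float) -> set:
    """Add border neighbors whose closed-neighborhood density exceeds the
    fluff threshold; fluffed nodes are not marked visited."""
    added = set()
    for v in list(members):
        for u in net.neighbors(v):
            if u in members or u in added or u in visited:
                continue
            closed = net.subgraph(set(net.neighbors(u)) | {u})
            if _density(closed) > fluff_density:
                added.add(u)
    return members | added


def find_complexes(
    net: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.5,
) -> list[Motif]:
    """Detect dense complexes by seeded expansion over vertex weights.

    Seeds are visited in descending weight order (ties by node id); only
    vertices with positive weight may seed — a weight-0 seed would admit
    every weight-0 neighbor and sweep up arbitrarily sparse structure.
    From each seed, a breadth-first expansion includes unvisited neighbors
    with weight >= seed_weight * (1 - vwp); every included vertex is marked
    visited, so complexes never overlap.  Complexes with fewer than 3
    members after the optional haircut are discarded.  Survivors are scored
    density * size and ranked descending (ties by seed id).
    """
    if not 0.0 <= vwp < 1.0:
        raise ValueError(f"vwp must be in [0, 1), got {vwp}")
    weights = vertex_weights(net)
    visited: set = set()
    raw: list[tuple[str, set]] = []

    for seed in sorted(weights, key=lambda v: (-weights[v], v)):
        if seed in visited or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - vwp)
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        while frontier:
            nxt = []
            for v in frontier:
                for u in net.neighbors(v):
                    if u not in visited and weights[u] >= threshold:
                        visited.add(u)
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
        raw.append((seed, members))

    motifs = []
    for seed, members in raw:
        if haircut:
            members = _haircut(net, members, seed)
        if fluff:
            members = _fluff(net, members, visited, fluff_density)
        if len(members) < MIN_COMPLEX_SIZE:
            continue
        sub = net.subgraph(members)
        dens = _density(sub)
        motifs.append(
            Motif(
                member_nodes=frozenset(members),
                seed_node=seed,
                density=dens,
                score=dens * len(members),
            )
        )

    motifs.sort(key=lambda m: (-m.score, m.seed_node))
    return [
        Motif(m.member_nodes, m.seed_node, m.density, m.score, rank=i + 1)
        for i, m in enumerate(motifs)
    ]


def top_motifs(complexes: list[Motif], n: int = 10) -> list[Motif]:
    """The first min(n, available) complexes by rank."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sorted(complexes, key=lambda m: m.rank)[:n]


def write_motif_table(motifs: list[Motif], path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tscore\tsize\tdensity\tseed\tmembers\n")
        for m in motifs:
            fh.write(
                f"{m.rank}\t{m.score:.6g}\t{len(m)}\t{m.density:.6g}\t"
                f"{m.seed_node}\t{','.join(sorted(m.member_nodes))}\n"
            )
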