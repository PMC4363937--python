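"""Hub/bottleneck centrality, index-gene neighborhoods, candidate nomination.

"Hubs" are ranked by degree and "bottlenecks" by (unnormalized, unweighted)
betweenness centrality.  Candidate co-signaling genes are nominated as the
intersection of: membership in the top hubs or top bottlenecks, proximity to
the index gene, and — when the index gene itself sits inside a detected
dense motif — co-membership in such a motif.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import pandas as pd

from .motifs import Motif

logger = logging.getLogger(__name__)

__all__ = ["centrality", "shortest_paths", "index_neighborhood", "nominate_candidates"]

UNREACHABLE = math.inf


def centrality(net: nx.Graph, index: str | None = None) -> pd.DataFrame:
    """Degree and betweenness table with hub/bottleneck ranks.

    Betweenness(v) = sum over unordered pairs s != v != t of the fraction of
    shortest s-t paths through v (unnormalized).  ``hub_rank`` orders by
    descending degree, ``bottleneck_rank`` by descending betweenness; ties
    broken by lexicographic node id.  If ``index`` is given, the BFS distance
    of every node to it is attached (inf when unreachable).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(net.nodes)
    deg = dict(net.degree())
    btw = nx.betweenness_centrality(net, normalized=False)

    df = pd.DataFrame(
        {
            "node": nodes,
            "degree": [deg[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
        }
    )
    df = df.sort_values(["degree", "node"], ascending=[False, True]).reset_index(drop=True)
    df["hub_rank"] = range(1, len(df) + 1)
    df = df.sort_values(["betweenness", "node"], ascending=[False, True]).reset_index(
        drop=True
    )
    df["bottleneck_rank"] = range(1, len(df) + 1)

    if index is not None:
        if index not in net:
            raise KeyError(f"index gene {index!r} not in network")
        dist = nx.single_source_shortest_path_length(net, index)
        df["distance_to_index"] = [dist.get(v, UNREACHABLE) for v in df["node"]]

    return df.sort_values("node").reset_index(drop=True)


_EPS = 1e-6  # keeps confidence-1.0 edges at a small positive cost


def shortest_paths(
    net: nx.Graph, source: str, weighted: bool = False
) -> tuple[dict, dict]:
    """Distances and predecessors from ``source``.

    Unweighted mode is plain BFS.  Weighted mode runs Dijkstra with edge
    cost 1 - confidence + eps, so higher-confidence interactions are
    preferred.  Unreachable nodes are absent from the returned maps.
    """
    if source not in net:
        raise KeyError(f"source {source!r} not in network")
    if not weighted:
        dist = nx.single_source_shortest_path_length(net, source)
        pred = dict(nx.bfs_predecessors(net, source))
        return dict(dist), pred

    def cost(u, v, d):
        return 1.0 - d.get("confidence", 0.0) + _EPS

    dist, paths = nx.single_source_dijkstra(net, source, weight=cost)
    pred = {v: p[-2] for v, p in paths.items() if len(p) >= 2}
    return dist, pred


def index_neighborhood(net: nx.Graph, index: str, radius: int = 1) -> nx.Graph:
    """Induced subgraph on nodes within BFS distance ``radius`` of the index."""
    if index not in net:
        raise KeyError(f"index gene {index!r} not in network")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    dist = nx.single_source_shortest_path_length(net, index, cutoff=radius)
    sub = nx.Graph(net.subgraph(dist.keys()))
    sub.graph["name"] = f"{net.graph.get('name', 'network')}_nbhd_{index}_r{radius}"
    return sub


def nominate_candidates(
    table: pd.DataFrame,
    motifs: list[Motif],
    index: str,
    top_h: int = 10,
    top_b: int = 10,
    max_dist: int = 2,
) -> pd.DataFrame:
    """Intersect top hubs/bottlenecks with the index gene's neighborhood.

    A node is a candidate when it (a) sits in the top ``top_h`` hubs OR the
    top ``top_b`` bottlenecks, (b) lies within ``max_dist`` of the index
    gene, and (c) — only when at least one detected motif contains the index
    gene — belongs to such a motif.  The index gene itself is excluded.
    Each candidate carries flags for the criteria it met; ordering is by
    (distance, best rank, node id), so an empty frame is a valid result.
    """
    if "distance_to_index" not in table.columns:
        raise ValueError("centrality table lacks distance_to_index; pass index= to centrality()")
    if index not in set(table["node"]):
        raise KeyError(f"index gene {index!r} not in centrality table")

    index_motifs = [m for m in motifs if index in m.member_nodes]
    motif_members: set = set()
    for m in index_motifs:
        motif_members |= set(m.member_nodes)

    rows = []
    for rec in table.itertuples(index=False):
        if rec.node == index:
            continue
        is_hub = rec.hub_rank <= top_h
        is_bottleneck = rec.bottleneck_rank <= top_b
        near = rec.distance_to_index <= max_dist
        in_motif = rec.node in motif_members
        qualifies = (is_hub or is_bottleneck) and near
        if index_motifs:
            qualifies = qualifies and in_motif
        if qualifies:
            rows.append(
                {
                    "node": rec.node,
                    "distance": rec.distance_to_index,
                    "top_hub": is_hub,
                    "top_bottleneck": is_bottleneck,
                    "in_index_motif": in_motif,
                    "hub_rank": rec.hub_rank,
                    "bottleneck_rank": rec.bottleneck_rank,
                }
            )
    cols = ["node", "distance", "top_hub", "top_bottleneck", "in_index_motif",
            "hub_rank", "bottleneck_rank"]
    out = pd.DataFrame(rows, columns=cols)
    if len(out):
        out["best_rank"] = out[["hub_rank", "bottleneck_rank"]].min(axis=1)
        out = out.sort_values(["distance", "best_rank", "node"]).reset_index(drop=True)
    return out
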