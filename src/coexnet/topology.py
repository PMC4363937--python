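"""Topological summary statistics and Erdős–Rényi baselines.

NOTE on the degree convention: ``k_mean`` here is **L/N — edges per node —
half the conventional mean degree 2L/N**.  This matches the convention of
the summary tables this module mirrors (every printed column satisfies
k = L/N; none satisfies 2L/N) and is kept deliberately.  The closed-form ER
path-length approximation ln(N)/ln(k) is evaluated under the same
convention.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["TopologySummary", "summarize", "er_random", "er_expectations",
           "write_topology_table"]


@dataclass
class TopologySummary:
    """N, L, mean degree (L/N convention), mean clustering, path length."""

    name: str
    n_nodes: int
    n_edges: int
    k_mean: float
    c_mean: float
    l_char: float
    n_components: int
    coverage_note: str

    def row(self) -> str:
        return (
            f"{self.name}\t{self.n_nodes}\t{self.n_edges}\t{self.k_mean:.4g}\t"
            f"{self.c_mean:.4g}\t{self.l_char:.4g}\t{self.n_components}"
        )


def summarize(net: nx.Graph, name: str | None = None) -> TopologySummary:
    """Topological summary of an undirected network.

    * ``k_mean`` = L/N (edges per node; see module note).
    * ``c_mean`` = mean Watts–Strogatz local clustering over nodes of
      degree >= 2 only (degree-0/1 nodes have no neighbor pair to close and
      are excluded rather than counted as zeros).
    * ``l_char`` = mean shortest-path length over all unordered connected
      pairs of the largest connected component, by breadth-first search.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("cannot summarize an empty network")
    m = net.number_of_edges()

    deg2 = [v for v in net.nodes if net.degree(v) >= 2]
    c_mean = (
        sum(nx.clustering(net, deg2).values()) / len(deg2) if deg2 else 0.0
    )

    components = list(nx.connected_components(net))
    lcc = net.subgraph(max(components, key=len))
    if lcc.number_of_nodes() > 1:
        l_char = nx.average_shortest_path_length(lcc)
    else:
        l_char = 0.0

    return TopologySummary(
        name=name or net.graph.get("name", "network"),
        n_nodes=n,
        n_edges=m,
        k_mean=m / n,
        c_mean=c_mean,
        l_char=l_char,
        n_components=len(components),
        coverage_note=(
            "k=L/N; C over degree>=2 nodes; l over largest component"
        ),
    )


def er_random(n: int, m: int, seed: int = 0) -> nx.Graph:
    """Uniform G(n, m): exactly m distinct edges sampled uniformly, seeded."""
    if m > n * (n - 1) // 2:
        raise ValueError(f"m={m} exceeds C({n},2)={n*(n-1)//2}")
    g = nx.gnm_random_graph(n, m, seed=seed)
    g.graph["name"] = f"ER_n{n}_m{m}"
    return g


class ERExpectations(NamedTuple):
    k_expected: float
    c_expected: float
    l_expected: float


def er_expectations(n: int, m: int) -> ERExpectations:
    """Closed-form G(n, m) expectations under the L/N degree convention.

    k = m/n; C = edge density m/C(n,2); l ~ ln(n)/ln(k), the small-world
    approximation for the characteristic path length.  When m <= n the log
    ratio is undefined (k <= 1) and l is returned as NaN with a warning.
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 and m >= 1")
    k = m / n
    c = m / (n * (n - 1) / 2)
    if k <= 1.0:
        warnings.warn(f"m/n = {k:.3g} <= 1: ER path-length approximation undefined")
        l = float("nan")
    else:
        l = math.log(n) / math.log(k)
    return ERExpectations(k_expected=k, c_expected=c, l_expected=l)


def write_topology_table(summaries: list[TopologySummary], path) -> None:
    """One row per network, columns mirroring the N/L/k/C/l table layout."""
    with open(path, "w") as fh:
        fh.write("network\tN\tL\tk\tC\tl\tcomponents\n")
        for s in summaries:
            fh.write(s.row() + "\n")
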