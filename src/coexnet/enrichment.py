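"""Over-representation analysis of motif gene sets.

Each detected complex is tested against an annotation collection (GMT) with
the upper-tail hypergeometric test — P(X >= overlap) when ``query_size``
genes are drawn from a universe containing ``term_size`` annotated genes —
followed by Benjamini–Hochberg adjustment across the collection.  The
default universe is the analysis network's node set, i.e. enrichment is
judged within the reconstructed network rather than against the genome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .motifs import Motif
from .ranking import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeom_enrich",
    "annotate_motifs",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional universe they live in."""

    sets: list[GeneSet]
    universe: frozenset | None = None
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene-set names in collection")
        if self.universe is not None:
            self.universe = frozenset(self.universe)
            for s in self.sets:
                if not s.members <= self.universe:
                    raise ValueError(f"set {s.name!r} has members outside the universe")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB member genes."""
    sets, desc = [], {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            members = frozenset(g for g in parts[2:] if g)
            if not members:
                continue
            sets.append(GeneSet(name=parts[0], members=members))
            desc[parts[0]] = parts[1]
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection.sets:
            desc = collection.descriptions.get(s.name, "na")
            fh.write(f"{s.name}\t{desc}\t" + "\t".join(sorted(s.members)) + "\n")


def hypergeom_enrich(
    query: GeneSet, collection: GeneSetCollection, universe: frozenset
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in every term.

    Term members outside the universe are clipped with a warning; the query
    is likewise restricted to the universe.  Terms with zero overlap are
    reported with p = 1 (P(X >= 0) is certain).  q-values are
    Benjamini–Hochberg across all tested terms; rows sorted ascending by p.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    q_genes = query.members & universe
    if not q_genes:
        raise ValueError(f"query {query.name!r} shares no genes with the universe")

    M, n_query = len(universe), len(q_genes)
    rows = []
    n_clipped_terms, n_clipped_genes = 0, 0
    for term in collection:
        members = term.members & universe
        if len(members) < len(term.members):
            n_clipped_terms += 1
            n_clipped_genes += len(term.members) - len(members)
        if not members:
            continue
        overlap = q_genes & members
        k, n_term = len(overlap), len(members)
        # upper tail: P(X >= k) for X ~ Hypergeom(M, n_term, n_query)
        p = float(stats.hypergeom.sf(k - 1, M, n_term, n_query)) if k > 0 else 1.0
        rows.append(
            {
                "term": term.name,
                "overlap": k,
                "term_size": n_term,
                "query_size": n_query,
                "universe_size": M,
                "p_value": min(p, 1.0),
                "overlap_genes": ",".join(sorted(overlap)),
            }
        )
    if n_clipped_terms:
        warnings.warn(
            f"{n_clipped_genes} gene(s) outside the universe clipped from "
            f"{n_clipped_terms} term(s)"
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["fdr_q"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["p_value", "term"]).reset_index(drop=True)


def annotate_motifs(
    motifs: list[Motif],
    collection: GeneSetCollection,
    universe: frozenset,
    top_terms: int = 4,
) -> dict[int, pd.DataFrame]:
    """Per-motif enrichment: the ``top_terms`` lowest-q terms for each motif.

    ``universe`` should be the analysis network's node set.  Returns a map
    from motif rank to its (possibly shorter than ``top_terms``) table.
    """
    if not motifs:
        raise ValueError("no motifs to annotate")
    out = {}
    for m in motifs:
        query = GeneSet(name=f"motif_{m.rank}", members=m.member_nodes)
        table = hypergeom_enrich(query, collection, universe)
        if not table.empty:
            table = table.sort_values(["fdr_q", "p_value", "term"]).head(top_terms)
            table = table.reset_index(drop=True)
        out[m.rank] = table
    return out


def write_enrichment_tables(tables: dict[int, pd.DataFrame], path) -> None:
    """Flat report: one block of rows per motif, mirroring a
    few-terms-per-module table layout."""
    frames = []
    for rank, df in sorted(tables.items()):
        df = df.copy()
        df.insert(0, "motif", rank)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
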