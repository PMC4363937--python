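"""Synthetic data with planted structure for every pipeline stage.

The generator emulates the study design the pipeline targets: a small
two-group expression experiment (3 pooled control vs 3 pooled stressed
samples by default) on a few hundred to a few thousand genes, a mined
interaction edge list with confidence scores in [0, 1], an external
co-expression gene list, and GMT annotations.  Planted structure — a
co-expressed module around the index gene, an anti-correlated module,
differential-expression sets, dense cliques and a designated hub — is
recorded in a :class:`SimulationTruth` so recovery can be scored exactly.

Expression is simulated on a post-log additive Gaussian scale: downstream
ranking uses correlations and rank statistics, which are insensitive to the
raw intensity scale, so probe-level simulation would add nothing testable.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .network_build import InteractionEdge
from .ranking import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationTruth",
    "simulate_expression",
    "simulate_interactions",
    "simulate_annotations",
    "simulate_candidate_network",
    "write_bundle",
]

BASELINE = 8.0  # log2-like baseline intensity


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset."""

    index_gene: str = ""
    pos_module: frozenset = frozenset()
    neg_module: frozenset = frozenset()
    de_up: frozenset = frozenset()
    de_down: frozenset = frozenset()
    planted_cliques: list = field(default_factory=list)
    true_edges: frozenset = frozenset()
    decoy_edges: frozenset = frozenset()
    hub_gene: str = ""
    universe: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pos_module & self.neg_module:
            raise ValueError("pos_module and neg_module overlap")
        if self.index_gene and self.index_gene in (self.pos_module | self.neg_module):
            raise ValueError("index gene must not be inside a planted module")
        if self.universe:
            for clique in self.planted_cliques:
                if not set(clique) <= set(self.universe):
                    raise ValueError("planted clique outside the gene universe")

    def to_json(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, frozenset):
                d[k] = sorted(v) if k not in ("true_edges", "decoy_edges") else sorted(
                    map(list, v)
                )
        d["planted_cliques"] = [sorted(c) for c in self.planted_cliques]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{str(i).zfill(width)}" for i in range(n)]


def simulate_expression(
    n_genes: int = 1000,
    n_per_group: int = 3,
    pos_size: int = 50,
    neg_size: int = 50,
    de_size: int = 50,
    rho: float = 0.9,
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Simulate a two-group expression matrix with planted co-expression.

    A latent factor (one value per sample) is shared between the index gene
    and the planted positive module: the index gene's profile IS the factor,
    each pos-module gene is rho*factor + sqrt(1-rho^2)*noise_sd*eps, and each
    neg-module gene carries the negated factor the same way, so the expected
    correlation with the index gene is +/-rho when noise_sd = 1 (and exactly
    +/-1 at rho = 1, noise_sd = 0).  ``de_up``/``de_down`` genes receive a
    +/-``effect_size`` mean shift in the stress samples.  All remaining
    genes are independent noise.  Identical seed => identical matrix.
    """
    if n_genes <= pos_size + neg_size + 1:
        raise ValueError("n_genes must exceed pos_size + neg_size + 1")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")

    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    n_samples = 2 * n_per_group
    samples = [f"control_{i+1}" for i in range(n_per_group)] + [
        f"stress_{i+1}" for i in range(n_per_group)
    ]
    classes = ["control"] * n_per_group + ["stress"] * n_per_group

    index_gene = genes[0]
    pos = genes[1 : 1 + pos_size]
    neg = genes[1 + pos_size : 1 + pos_size + neg_size]
    rest = genes[1 + pos_size + neg_size :]
    de_size = min(de_size, len(rest) // 2)
    de_up = rest[:de_size]
    de_down = rest[de_size : 2 * de_size]

    factor = rng.standard_normal(n_samples)
    X = BASELINE + noise_sd * rng.standard_normal((n_genes, n_samples))

    gidx = {g: i for i, g in enumerate(genes)}
    X[gidx[index_gene]] = BASELINE + factor
    mix = np.sqrt(1.0 - rho**2)
    for g in pos:
        X[gidx[g]] = BASELINE + rho * factor + mix * noise_sd * rng.standard_normal(
            n_samples
        )
    for g in neg:
        X[gidx[g]] = BASELINE - rho * factor + mix * noise_sd * rng.standard_normal(
            n_samples
        )
    stress_cols = np.arange(n_per_group, n_samples)
    for g in de_up:
        X[gidx[g], stress_cols] += effect_size
    for g in de_down:
        X[gidx[g], stress_cols] -= effect_size

    expr = ExpressionMatrix(
        values=pd.DataFrame(X, index=genes, columns=samples), classes=classes
    )
    truth = SimulationTruth(
        index_gene=index_gene,
        pos_module=frozenset(pos),
        neg_module=frozenset(neg),
        de_up=frozenset(de_up),
        de_down=frozenset(de_down),
        universe=frozenset(genes),
        seed=seed,
    )
    return expr, truth


def _draw_conf(rng: np.random.Generator, params, size: int) -> np.ndarray:
    """Beta(a, b) confidences, or a point mass when a bare float is given."""
    if isinstance(params, (int, float)):
        return np.full(size, float(params))
    a, b = params
    return rng.beta(a, b, size=size)


def simulate_interactions(
    genes: list[str],
    hub_gene: str,
    n_cliques: int = 8,
    clique_size_range: tuple[int, int] = (4, 6),
    conf_true=(8.0, 2.0),
    conf_decoy=(2.0, 8.0),
    decoy_fraction: float = 0.3,
    seed: int = 0,
    index_gene: str | None = None,
    index_in_first_clique: bool = False,
    hub_in_first_clique: bool = False,
    clique_pool: list[str] | None = None,
) -> tuple[list[InteractionEdge], SimulationTruth]:
    """Simulate a mined interaction edge list with planted dense structure.

    Disjoint cliques are planted among ``genes``; ``hub_gene`` is attached
    by one edge to each clique, guaranteeing it the top degree.  True edges
    draw confidence from a high-mean distribution (default Beta(8,2)),
    decoys from a low-mean one (default Beta(2,8)) — chosen so a 0.7 cutoff
    separates them sharply; bare floats give point masses.  Decoys are
    uniform random non-edges making up ``decoy_fraction`` of the final list.

    ``index_in_first_clique``/``hub_in_first_clique`` force the index gene
    (and optionally the hub) into the first planted clique — the "acute"
    benchmark geometry where a hub shares a dense motif with the index gene.
    """
    if not genes:
        raise ValueError("genes must be nonempty")
    if hub_gene not in genes:
        raise ValueError(f"hub gene {hub_gene!r} not among genes")
    if not 0.0 <= decoy_fraction < 1.0:
        raise ValueError(f"decoy_fraction must be in [0, 1), got {decoy_fraction}")
    lo, hi = clique_size_range
    if lo < 3 or hi < lo:
        raise ValueError("clique sizes must be >= 3 and lo <= hi")

    rng = np.random.default_rng(seed)
    reserved = {hub_gene}
    if index_gene is not None:
        reserved.add(index_gene)
    # cliques are drawn from clique_pool when given (e.g. the planted module
    # genes, emulating interactions mined around the extracted lists);
    # decoys always range over the full gene universe
    pool = [g for g in (clique_pool if clique_pool is not None else genes)
            if g not in reserved]
    rng.shuffle(pool)

    cliques: list[frozenset] = []
    cursor = 0
    for c in range(n_cliques):
        size = int(rng.integers(lo, hi + 1))
        forced = []
        if c == 0 and index_in_first_clique and index_gene is not None:
            forced.append(index_gene)
        if c == 0 and hub_in_first_clique:
            forced.append(hub_gene)
        take = size - len(forced)
        if cursor + take > len(pool):
            raise ValueError("not enough genes for the requested cliques")
        members = forced + pool[cursor : cursor + take]
        cursor += take
        cliques.append(frozenset(members))

    true_keys = set()
    anchors = []
    for clique in cliques:
        for a, b in itertools.combinations(sorted(clique), 2):
            true_keys.add((a, b))
        # hub attachment: one edge to the clique's first member; the index
        # gene never anchors, so hub-index adjacency only arises through
        # shared clique membership
        candidates = [g for g in sorted(clique) if g != index_gene]
        anchor = candidates[0] if candidates else sorted(clique)[0]
        anchors.append(anchor)
        if anchor != hub_gene:
            true_keys.add(tuple(sorted((hub_gene, anchor))))

    n_true = len(true_keys)
    n_decoy = int(round(decoy_fraction / (1.0 - decoy_fraction) * n_true))
    decoy_keys: set = set()
    gene_arr = np.asarray(genes, dtype=object)
    guard = 0
    while len(decoy_keys) < n_decoy and guard < 100 * n_decoy + 1000:
        a, b = rng.choice(gene_arr, size=2, replace=False)
        key = tuple(sorted((str(a), str(b))))
        if key not in true_keys:
            decoy_keys.add(key)
        guard += 1

    true_sorted = sorted(true_keys)
    decoy_sorted = sorted(decoy_keys)
    conf_t = _draw_conf(rng, conf_true, len(true_sorted))
    conf_d = _draw_conf(rng, conf_decoy, len(decoy_sorted))

    edges = [
        InteractionEdge(a, b, float(np.clip(c, 0, 1)), "physical")
        for (a, b), c in zip(true_sorted, conf_t)
    ] + [
        InteractionEdge(a, b, float(np.clip(c, 0, 1)), "text_mined")
        for (a, b), c in zip(decoy_sorted, conf_d)
    ]

    truth = SimulationTruth(
        index_gene=index_gene or "",
        planted_cliques=cliques,
        true_edges=frozenset(true_keys),
        decoy_edges=frozenset(decoy_keys),
        hub_gene=hub_gene,
        universe=frozenset(genes),
        seed=seed,
    )
    return edges, truth


def simulate_annotations(
    truth: SimulationTruth,
    n_background_terms: int = 20,
    term_size_range: tuple[int, int] = (5, 30),
    contamination: int = 0,
    seed: int = 0,
) -> GeneSetCollection:
    """GMT-style annotations: one term per planted clique plus random terms.

    Each planted term contains its clique's genes, optionally with
    ``contamination`` extra random genes mixed in.  Background terms are
    drawn without replacement from the gene universe, so no term can exceed
    the universe size.
    """
    if not truth.planted_cliques:
        raise ValueError("truth has no planted cliques to annotate")
    rng = np.random.default_rng(seed)
    universe = sorted(truth.universe)
    sets, desc = [], {}
    for i, clique in enumerate(truth.planted_cliques, 1):
        members = set(clique)
        if contamination > 0:
            extra = [g for g in universe if g not in members]
            members |= set(rng.choice(extra, size=min(contamination, len(extra)),
                                      replace=False))
        name = f"planted_term_{i:02d}"
        sets.append(GeneSet(name=name, members=frozenset(members)))
        desc[name] = "planted clique annotation"
    lo, hi = term_size_range
    for j in range(1, n_background_terms + 1):
        size = int(rng.integers(lo, min(hi, len(universe)) + 1))
        members = frozenset(rng.choice(universe, size=size, replace=False))
        name = f"background_term_{j:02d}"
        sets.append(GeneSet(name=name, members=members))
        desc[name] = "random background"
    return GeneSetCollection(sets=sets, universe=frozenset(universe),
                             descriptions=desc)


def simulate_candidate_network(
    seed: int = 0,
    scenario: str = "acute",
    n_genes: int = 80,
    n_cliques: int = 4,
):
    """Benchmark geometry for candidate nomination.

    ``acute``: a designated hub shares the index gene's clique and is
    attached to every other clique — the planted answer is the hub itself
    (a Stat3-like co-hub adjacent to the index gene).  ``repeated``: the
    index gene sits in a clique whose other members are NOT global hubs;
    the planted answer is the index gene's top-degree clique partner (a
    Prlh-like co-motif member).  Returns
    (edges, truth, index_gene, expected_candidate).

    Planted edges carry confidence 0.95 (a point mass above the 0.7
    cutoff): the benchmark scores the nomination logic on a geometry the
    construction guarantees, so the trusted edges must survive the
    confidence filter; decoys keep the default low-mean distribution.
    """
    conf_true = 0.95
    genes = _gene_names(n_genes)
    index_gene, hub_gene = genes[0], genes[1]
    if scenario == "acute":
        edges, truth = simulate_interactions(
            genes,
            hub_gene=hub_gene,
            n_cliques=n_cliques,
            clique_size_range=(5, 5),
            conf_true=conf_true,
            decoy_fraction=0.25,
            seed=seed,
            index_gene=index_gene,
            index_in_first_clique=True,
            hub_in_first_clique=True,
        )
        expected = hub_gene
    elif scenario == "repeated":
        edges, truth = simulate_interactions(
            genes,
            hub_gene=hub_gene,  # hub exists but outside the index clique
            n_cliques=n_cliques,
            clique_size_range=(5, 5),
            conf_true=conf_true,
            decoy_fraction=0.25,
            seed=seed,
            index_gene=index_gene,
            index_in_first_clique=True,
            hub_in_first_clique=False,
        )
        # the planted answer: the index gene's clique partner that also
        # anchors the hub attachment (degree 5 vs 4 for plain members)
        first = truth.planted_cliques[0]
        expected = next(g for g in sorted(first) if g != index_gene)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return edges, truth, index_gene, expected


def write_bundle(
    outdir,
    n_genes: int = 600,
    seed: int = 42,
    rho: float = 0.9,
    n_cliques: int = 8,
    decoy_fraction: float = 0.3,
    n_external: int = 50,
) -> dict:
    """Write a complete synthetic input bundle for an end-to-end run.

    Produces expression.tsv, interactions.tsv, external_genes.txt,
    annotations.gmt and truth.json under ``outdir``; returns the paths plus
    the truth objects.  Sub-seeds are derived deterministically from
    ``seed``.
    """
    from pathlib import Path

    from .network_build import write_edges

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]

    expr, expr_truth = simulate_expression(
        n_genes=n_genes, rho=rho, seed=seeds[0]
    )
    genes = expr.gene_ids
    hub_gene = sorted(expr_truth.pos_module)[0]
    module_genes = sorted(
        expr_truth.pos_module | expr_truth.neg_module
        | expr_truth.de_up | expr_truth.de_down
    )
    edges, net_truth = simulate_interactions(
        genes,
        hub_gene=hub_gene,
        n_cliques=n_cliques,
        decoy_fraction=decoy_fraction,
        seed=seeds[1],
        index_gene=expr_truth.index_gene,
        index_in_first_clique=True,
        hub_in_first_clique=True,
        clique_pool=module_genes,
    )
    annotations = simulate_annotations(net_truth, seed=seeds[2])

    rng = np.random.default_rng(seeds[3])
    pos_sorted = sorted(expr_truth.pos_module)
    external = list(pos_sorted[: n_external // 2])
    others = [g for g in genes if g not in expr_truth.pos_module
              and g != expr_truth.index_gene]
    external += list(rng.choice(others, size=n_external - len(external),
                                replace=False))

    expr_path = outdir / "expression.tsv"
    edge_path = outdir / "interactions.tsv"
    ext_path = outdir / "external_genes.txt"
    gmt_path = outdir / "annotations.gmt"
    truth_path = outdir / "truth.json"

    expr.to_tsv(expr_path)
    write_edges(edges, edge_path)
    ext_path.write_text("\n".join(sorted(external)) + "\n")
    from .enrichment import write_gmt

    write_gmt(annotations, gmt_path)
    net_truth.to_json(truth_path)

    return {
        "expression": str(expr_path),
        "edges": str(edge_path),
        "external": str(ext_path),
        "gmt": str(gmt_path),
        "truth": str(truth_path),
        "index_gene": expr_truth.index_gene,
        "hub_gene": hub_gene,
        "expr_truth": expr_truth,
        "net_truth": net_truth,
    }
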