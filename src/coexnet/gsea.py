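"""Weighted Kolmogorov–Smirnov enrichment scores with permutation normalization.

The enrichment score (ES) of a gene set against a ranked list is the signed
maximal deviation of a running sum that steps up at set members ("hits", by
|score|^p weight) and down at non-members ("misses", uniformly).  With
weight exponent p = 0 this is exactly the classic two-sample KS statistic
between hit and miss rank positions.  Normalized scores (NES), empirical
p-values and FDR q-values come from a permutation null — by default random
gene sets of matching size, because a 3-vs-3 sample design leaves phenotype
permutation degenerate (phenotype mode is still available).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .ranking import ExpressionMatrix, GeneSet, RankedList, rank_by_class

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "enrichment_score", "normalize_es", "write_gsea_report"]


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float = float("nan")
    p_value: float = float("nan")
    fdr_q: float = float("nan")
    leading_edge: frozenset = field(default_factory=frozenset)
    running_sum: np.ndarray | None = None
    n_members: int = 0
    nes_defined: bool = True


def _hit_increments(scores_at_hits: np.ndarray, weight_p: float) -> np.ndarray:
    """Normalized per-hit step sizes: |score|^p / sum(|score|^p)."""
    w = np.abs(scores_at_hits) ** weight_p
    total = w.sum()
    if total == 0:  # all hit scores zero: fall back to equal weights
        return np.full(len(w), 1.0 / len(w))
    return w / total


def _es_from_positions(
    positions: np.ndarray, hit_inc: np.ndarray, n: int
) -> tuple[float, int]:
    """Signed ES and the extremum position, from sorted hit positions only.

    Between hits the running sum decays linearly, so the extremum is attained
    either immediately after a hit or immediately before one; O(k) per set.
    """
    k = len(positions)
    miss = 1.0 / (n - k)
    cum_hit = np.cumsum(hit_inc)
    i = np.arange(k)
    after = cum_hit - (positions + 1 - (i + 1)) * miss  # value at each hit position
    before = np.concatenate(([0.0], cum_hit[:-1])) - (positions - i) * miss
    cand = np.concatenate((after, before))
    cand_pos = np.concatenate((positions, np.maximum(positions - 1, 0)))
    j = int(np.argmax(np.abs(cand)))
    return float(cand[j]), int(cand_pos[j])


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight_p: float = 1.0
) -> EnrichmentResult:
    """Compute the weighted KS enrichment score of ``gene_set`` along ``ranked``.

    Returns an :class:`EnrichmentResult` with ``es``, the full
    ``running_sum`` (length N, ends at 0 up to float error) and the
    ``leading_edge`` — the hits at or before the extremum for positive ES,
    at or after it for negative ES.

    Set members absent from the ranked list are dropped with a warning.
    A set with no overlap, or covering the whole list, is rejected.
    """
    if weight_p < 0:
        raise ValueError("weight_p must be non-negative")
    n = len(ranked)
    in_list = set(ranked.gene_ids)
    members = gene_set.members & in_list
    dropped = len(gene_set.members) - len(members)
    if dropped:
        warnings.warn(
            f"{gene_set.name}: {dropped} member(s) absent from ranked list, dropped"
        )
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} has no overlap with ranked list")
    if len(members) == n:
        raise ValueError(
            f"gene set {gene_set.name!r} covers the entire ranked list "
            "(miss increment undefined)"
        )

    hit_mask = np.fromiter((g in members for g in ranked.gene_ids), bool, n)
    positions = np.flatnonzero(hit_mask)
    hit_inc = _hit_increments(ranked.scores[positions], weight_p)

    steps = np.full(n, -1.0 / (n - len(positions)))
    steps[positions] = hit_inc
    running = np.cumsum(steps)

    es, ext = _es_from_positions(positions, hit_inc, n)
    if es >= 0:
        lead = positions[positions <= ext]
    else:
        lead = positions[positions >= ext]
    leading = frozenset(ranked.gene_ids[i] for i in lead)

    return EnrichmentResult(
        set_name=gene_set.name,
        es=es,
        leading_edge=leading,
        running_sum=running,
        n_members=len(members),
    )


def _permuted_es(
    rng: np.random.Generator,
    abs_scores_p: np.ndarray,
    set_size: int,
    n_perm: int,
    n: int,
) -> np.ndarray:
    """ES under the gene-set null: random hit positions of matching size."""
    out = np.empty(n_perm)
    for b in range(n_perm):
        pos = np.sort(rng.choice(n, size=set_size, replace=False))
        w = abs_scores_p[pos]
        total = w.sum()
        inc = w / total if total > 0 else np.full(set_size, 1.0 / set_size)
        out[b], _ = _es_from_positions(pos, inc, n)
    return out


def normalize_es(
    ranked: RankedList,
    gene_sets: list[GeneSet],
    n_perm: int = 1000,
    weight_p: float = 1.0,
    scheme: str = "gene_set",
    seed: int = 0,
    expr: ExpressionMatrix | None = None,
    metric: str = "signal_to_noise",
    positive_class: str | None = None,
) -> list[EnrichmentResult]:
    """Fill in NES, empirical p and GSEA-style FDR q for each gene set.

    NES = ES / mean(|permuted ES of the same sign|).  The empirical p-value
    is the same-sign tail fraction with a +1 pseudo-count in numerator and
    denominator.  FDR q is the ratio of the pooled permuted-NES tail
    proportion to the observed-NES tail proportion, clipped to [0, 1].

    ``scheme='gene_set'`` permutes set membership; ``scheme='phenotype'``
    permutes the class labels of ``expr`` and re-ranks (requires ``expr``).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    results = [enrichment_score(ranked, gs, weight_p) for gs in gene_sets]
    n = len(ranked)

    if scheme == "gene_set":
        abs_p = np.abs(ranked.scores) ** weight_p
        # one permutation block per distinct set size, reused across sets
        perm_by_size: dict[int, np.ndarray] = {}
        perm_es = []
        for res in results:
            if res.n_members not in perm_by_size:
                perm_by_size[res.n_members] = _permuted_es(
                    rng, abs_p, res.n_members, n_perm, n
                )
            perm_es.append(perm_by_size[res.n_members])
    elif scheme == "phenotype":
        if expr is None:
            raise ValueError("phenotype scheme requires the expression matrix")
        labels = np.asarray(expr.classes)
        perm_mat = np.empty((len(results), n_perm))
        for b in range(n_perm):
            shuffled = ExpressionMatrix(
                values=expr.values, classes=list(rng.permutation(labels))
            )
            try:
                r_b = rank_by_class(shuffled, metric=metric, positive_class=positive_class)
            except ValueError:  # a permutation may collapse a class; reshuffle
                r_b = rank_by_class(expr, metric=metric, positive_class=positive_class)
            for i, gs in enumerate(gene_sets):
                perm_mat[i, b] = enrichment_score(r_b, gs, weight_p).es
        perm_es = [perm_mat[i] for i in range(len(results))]
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    # per-set sign-matched normalization
    pooled_nes = []
    for res, perms in zip(results, perm_es):
        same_sign = perms[perms >= 0] if res.es >= 0 else perms[perms < 0]
        if len(same_sign) == 0:
            res.nes = float("nan")
            res.nes_defined = False
            res.p_value = float("nan")
            warnings.warn(
                f"{res.set_name}: no same-sign permutations; NES undefined"
            )
            continue
        denom = np.abs(same_sign).mean()
        res.nes = res.es / denom if denom > 0 else float("nan")
        res.p_value = (1 + int(np.sum(np.abs(same_sign) >= abs(res.es)))) / (
            1 + len(same_sign)
        )
        pos_mean = np.abs(perms[perms >= 0]).mean() if np.any(perms >= 0) else np.nan
        neg_mean = np.abs(perms[perms < 0]).mean() if np.any(perms < 0) else np.nan
        norm = np.where(perms >= 0, perms / pos_mean, perms / neg_mean)
        pooled_nes.append(norm[np.isfinite(norm)])

    if pooled_nes:
        pool = np.concatenate(pooled_nes)
        obs = np.array([r.nes for r in results if r.nes_defined])
        for res in results:
            if not res.nes_defined:
                continue
            if res.nes >= 0:
                num_pool = pool[pool >= 0]
                num = np.mean(num_pool >= res.nes) if len(num_pool) else 0.0
                den_obs = obs[obs >= 0]
                den = np.mean(den_obs >= res.nes) if len(den_obs) else 1.0
            else:
                num_pool = pool[pool < 0]
                num = np.mean(num_pool <= res.nes) if len(num_pool) else 0.0
                den_obs = obs[obs < 0]
                den = np.mean(den_obs <= res.nes) if len(den_obs) else 1.0
            res.fdr_q = float(np.clip(num / den if den > 0 else 1.0, 0.0, 1.0))
    return results


def write_gsea_report(results: list[EnrichmentResult], path) -> None:
    """Tab-separated report: set, size, es, nes, p, q, leading-edge genes."""
    with open(path, "w") as fh:
        fh.write("set\tsize\tes\tnes\tp_value\tfdr_q\tleading_edge\n")
        for r in sorted(results, key=lambda r: (r.p_value, r.set_name)):
            lead = ",".join(sorted(r.leading_edge))
            fh.write(
                f"{r.set_name}\t{r.n_members}\t{r.es:.6g}\t{r.nes:.6g}\t"
                f"{r.p_value:.6g}\t{r.fdr_q:.6g}\t{lead}\n"
            )
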