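"""Ranked gene lists and module extraction.

Two ranking modes drive the pipeline: correlation of every gene's profile
with a chosen *index gene* (the anchor of a co-expression neighborhood),
and a two-class contrast (signal-to-noise or mean difference) between the
control and stressed sample groups.  The top/bottom slices of these lists
are the gene "modules" that seed network reconstruction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "RankedList",
    "GeneSet",
    "rank_by_index_gene",
    "rank_by_class",
    "top_k",
    "write_rnk",
    "read_rnk",
]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with one class label per sample.

    ``values`` is a pandas DataFrame indexed by gene id with sample ids as
    columns.  ``classes`` assigns each sample to a group (for the two-class
    contrast exactly two distinct labels are required, but the container
    itself is label-agnostic).
    """

    values: pd.DataFrame
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:3].tolist()
            raise ValueError(f"duplicate gene ids in expression matrix: {dup}")
        if len(self.classes) != self.values.shape[1]:
            raise ValueError(
                f"classes has {len(self.classes)} labels for "
                f"{self.values.shape[1]} samples"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        """Write tab-separated text: header of sample ids, a second header
        line of class labels, then one row per gene."""
        with open(path, "w") as fh:
            fh.write("gene_id\t" + "\t".join(map(str, self.values.columns)) + "\n")
            fh.write("class\t" + "\t".join(self.classes) + "\n")
            for gene, row in self.values.iterrows():
                fh.write(str(gene) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            class_line = fh.readline().rstrip("\n").split("\t")
            if class_line[0] != "class":
                raise ValueError(f"{path}: second line must carry class labels")
            genes, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                genes.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        values = pd.DataFrame(rows, index=genes, columns=header[1:])
        return cls(values=values, classes=class_line[1:])


@dataclass
class RankedList:
    """Genes ordered by a ranking metric, best (highest) score first.

    Ties are broken by lexicographic gene id so the ordering is fully
    deterministic.
    """

    gene_ids: list[str]
    scores: np.ndarray
    metric_name: str = "score"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in ranked list")
        order = np.lexsort((np.asarray(self.gene_ids, dtype=object), -self.scores))
        self.gene_ids = [self.gene_ids[i] for i in order]
        self.scores = self.scores[order]

    def __len__(self) -> int:
        return len(self.gene_ids)

    def position(self, gene: str) -> int:
        return self.gene_ids.index(gene)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, self.metric_name: self.scores})


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene) -> bool:
        return gene in self.members


def rank_by_index_gene(
    expr: ExpressionMatrix, index_gene: str, method: str = "pearson"
) -> RankedList:
    """Rank all genes by correlation of their profile with the index gene.

    The score is the Pearson (or Spearman) correlation across *all* samples.
    The index gene itself is excluded from the output — it would trivially
    rank first.  Genes with zero variance across samples get score 0.

    Raises
    ------
    KeyError
        if ``index_gene`` is not in the matrix.
    ValueError
        if the index gene's profile is constant (correlation undefined)
        or fewer than 3 samples are available.
    """
    if index_gene not in expr.values.index:
        raise KeyError(f"index gene {index_gene!r} not in expression matrix")
    if expr.values.shape[1] < 3:
        raise ValueError("need at least 3 samples to rank by correlation")

    X = expr.values.to_numpy(dtype=float)
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")

    idx = expr.values.index.get_loc(index_gene)
    ref = X[idx]
    ref_c = ref - ref.mean()
    ref_norm = np.sqrt((ref_c**2).sum())
    if ref_norm == 0:
        raise ValueError(f"index gene {index_gene!r} has constant profile")

    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        cor = (Xc @ ref_c) / (norms * ref_norm)
    cor[norms == 0] = 0.0  # constant genes carry no signal
    cor = np.clip(cor, -1.0, 1.0)

    keep = np.arange(len(cor)) != idx
    return RankedList(
        gene_ids=[g for i, g in enumerate(expr.gene_ids) if keep[i]],
        scores=cor[keep],
        metric_name=f"{method}_r_vs_{index_gene}",
    )


# GSEA-style floor on each class standard deviation: sd is never allowed
# below 20% of |mean| (nor below 1e-8), so that near-constant probes do not
# produce explosive signal-to-noise scores.
_SD_FLOOR_FRAC = 0.2
_SD_FLOOR_ABS = 1e-8


def rank_by_class(
    expr: ExpressionMatrix,
    metric: str = "signal_to_noise",
    positive_class: str | None = None,
) -> RankedList:
    """Rank genes by a two-class contrast.

    ``signal_to_noise`` scores (mu_A - mu_B)/(sd_A + sd_B), with each class
    sd floored at max(0.2*|mu|, 1e-8); ``mean_difference`` scores mu_A - mu_B.
    Class A is ``positive_class`` (genes higher in that class score
    positively); by default the second class label in column order, so with
    columns ordered control-then-stress the stress-elevated genes rank top.
    """
    labels = list(dict.fromkeys(expr.classes))  # unique, order of appearance
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 class levels, got {labels}")
    if positive_class is None:
        positive_class = labels[1]
    if positive_class not in labels:
        raise ValueError(f"positive_class {positive_class!r} not among {labels}")
    other = labels[0] if positive_class == labels[1] else labels[1]

    cls = np.asarray(expr.classes)
    a_mask, b_mask = cls == positive_class, cls == other
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("each class needs >= 2 samples (variance undefined otherwise)")

    X = expr.values.to_numpy(dtype=float)
    mu_a, mu_b = X[:, a_mask].mean(axis=1), X[:, b_mask].mean(axis=1)

    if metric == "mean_difference":
        score = mu_a - mu_b
    elif metric == "signal_to_noise":
        sd_a = X[:, a_mask].std(axis=1, ddof=1)
        sd_b = X[:, b_mask].std(axis=1, ddof=1)
        sd_a = np.maximum(sd_a, np.maximum(_SD_FLOOR_FRAC * np.abs(mu_a), _SD_FLOOR_ABS))
        sd_b = np.maximum(sd_b, np.maximum(_SD_FLOOR_FRAC * np.abs(mu_b), _SD_FLOOR_ABS))
        score = (mu_a - mu_b) / (sd_a + sd_b)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    return RankedList(
        gene_ids=expr.gene_ids, scores=score, metric_name=f"{metric}_{positive_class}"
    )


def top_k(ranked: RankedList, k: int, direction: str = "top") -> GeneSet:
    """Extract the k best (``top``) or k worst (``bottom``) genes as a set.

    Boundary ties are broken by lexicographic gene id (the RankedList is
    already ordered that way).  A k beyond the list length clips with a
    warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(ranked)
    if k > n:
        warnings.warn(f"top_k: k={k} exceeds list length {n}; clipping")
        k = n
    if direction == "top":
        members = ranked.gene_ids[:k]
    elif direction == "bottom":
        # lowest scores; within equal scores keep lexicographic order
        order = np.lexsort((np.asarray(ranked.gene_ids, dtype=object), ranked.scores))
        members = [ranked.gene_ids[i] for i in order[:k]]
    else:
        raise ValueError(f"direction must be 'top' or 'bottom', got {direction!r}")
    return GeneSet(name=f"{ranked.metric_name}_{direction}{k}", members=frozenset(members))


def write_rnk(ranked: RankedList, path) -> None:
    """Write gene-id TAB score, descending (standard RNK layout)."""
    with open(path, "w") as fh:
        for g, s in zip(ranked.gene_ids, ranked.scores):
            fh.write(f"{g}\t{s:.10g}\n")


def read_rnk(path, metric_name: str = "rnk") -> RankedList:
    genes, scores = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            g, s = line.split("\t")[:2]
            genes.append(g)
            scores.append(float(s))
    return RankedList(gene_ids=genes, scores=np.array(scores), metric_name=metric_name)
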