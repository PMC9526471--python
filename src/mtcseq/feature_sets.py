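"""The eight candidate feature-set construction rules.

Eight gene lists compete in cross-validation, each built from the
dual-context DE results by a different pruning rule and each force-augmented
with the mandatory 34-gene cassette (5 legacy cassette genes + 29
literature-derived genes):

1. DE genes with adjusted p < 1e-6 (both contexts)
2. DE genes with adjusted p < 1e-6 and log2FC > 6 (both contexts)
3-5. average-linkage hierarchical clustering of DE genes (adjusted p < 0.01,
     both contexts) on correlation distance; pick the top 1 / 20% / 50%
     genes per cluster by FNAB adjusted p
6-8. recursive 2-medoid partitioning of the same DE genes (a reproducible
     stand-in for HOPACH-style recursive partitioning); pick the top
     10% / 20% / 50% per leaf cluster

Per-cluster picks use ceil on fractional counts, so nestedness
(3 within 4 within 5, 6 within 7 within 8) holds by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .containers import CountMatrix
from .diffexp import dual_context_de, size_factors


@dataclass
class CandidateFeatureSet:
    """One of the eight rule-built gene lists (cassette always included)."""

    set_id: int
    rule: str
    genes: list[str]
    mandatory_genes: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        if not 1 <= self.set_id <= 8:
            raise ValueError("set_id must be 1..8")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("genes must be unique")
        missing = set(self.mandatory_genes) - set(self.genes)
        if missing:
            raise ValueError(f"mandatory genes missing from set: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.genes)


def _finalize(set_id: int, rule: str, selected: list[str],
              mandatory: list[str]) -> CandidateFeatureSet:
    genes = list(dict.fromkeys(list(selected) + list(mandatory)))
    return CandidateFeatureSet(set_id=set_id, rule=rule, genes=genes,
                               mandatory_genes=list(mandatory))


def build_set_1_2(detable: pd.DataFrame,
                  mandatory: list[str]) -> tuple[CandidateFeatureSet,
                                                 CandidateFeatureSet]:
    """Sets 1 and 2: dual-context p < 1e-6, without / with log2FC > 6."""
    if len(detable) == 0:
        raise ValueError("empty DE table")
    s1 = dual_context_de(detable, p_cut=1e-6)
    s2 = dual_context_de(detable, p_cut=1e-6, fc_cut=6.0)
    return (
        _finalize(1, "dual-context adj_p<1e-6", s1, mandatory),
        _finalize(2, "dual-context adj_p<1e-6 & log2FC>6", s2, mandatory),
    )


def _rank_genes(detable: pd.DataFrame, genes: list[str]) -> list[str]:
    """Genes ordered by FNAB adjusted p (ties: larger |log2fc|, then id)."""
    fnab = detable[detable["context"] == "train_fnab"].set_index("gene_id")
    sub = fnab.loc[genes]
    order = sorted(
        genes,
        key=lambda g: (sub.at[g, "adj_p"], -abs(sub.at[g, "log2fc"]), g),
    )
    return order


def _log_expression(expression: CountMatrix, genes: list[str]) -> np.ndarray:
    """log2(normalized count + 1) for ``genes`` over training FNAB samples."""
    train = expression.cohort("train_fnab")
    sf = size_factors(train)
    idx = train.gene_index(genes)
    return np.log2(train.counts[idx, :] / sf[None, :] + 1.0)


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows, clipped to [0, 2]."""
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(x)
    c = np.nan_to_num(c, nan=0.0)  # constant rows: treat as uncorrelated
    np.fill_diagonal(c, 1.0)
    return np.clip(1.0 - c, 0.0, 2.0)


def _select_per_cluster(detable: pd.DataFrame, clusters: list[list[str]],
                        fraction: float | None, top_n: int | None = None
                        ) -> list[str]:
    """Top genes per cluster by FNAB adjusted p; ceil on fractional counts."""
    chosen: list[str] = []
    for members in clusters:
        ranked = _rank_genes(detable, members)
        k = top_n if top_n is not None else math.ceil(fraction * len(members))
        chosen.extend(ranked[:max(k, 1)])
    return chosen


def de_genes_for_clustering(detable: pd.DataFrame,
                            p_cut: float = 0.01) -> list[str]:
    """Dual-context DE genes feeding the clustering-based sets (3-8)."""
    return dual_context_de(detable, p_cut=p_cut)


def build_sets_3_5(detable: pd.DataFrame, expression: CountMatrix,
                   mandatory: list[str]) -> tuple[CandidateFeatureSet, ...]:
    """Sets 3-5: hierarchical clustering + top 1 / 20% / 50% per cluster.

    Average linkage on 1 - Pearson correlation of log2(normalized count + 1)
    across training FNAB samples; the tree is cut into
    ``k = max(2, ceil(sqrt(#DE genes)))`` clusters.
    """
    de = de_genes_for_clustering(detable)
    rules = {3: "hclust top-1 per cluster", 4: "hclust top-20% per cluster",
             5: "hclust top-50% per cluster"}
    if len(de) < 2:
        warnings.warn("fewer than 2 DE genes at adj_p<0.01; "
                      "falling back to mandatory-only sets")
        return tuple(_finalize(i, rules[i], [], mandatory) for i in (3, 4, 5))
    dist = _correlation_distance(_log_expression(expression, de))
    k = max(2, math.ceil(math.sqrt(len(de))))
    z = linkage(squareform(dist, checks=False), method="average")
    assignment = fcluster(z, t=min(k, len(de)), criterion="maxclust")
    clusters = [[g for g, a in zip(de, assignment) if a == c]
                for c in np.unique(assignment)]
    sets = (
        _finalize(3, rules[3],
                  _select_per_cluster(detable, clusters, None, top_n=1),
                  mandatory),
        _finalize(4, rules[4],
                  _select_per_cluster(detable, clusters, 0.2), mandatory),
        _finalize(5, rules[5],
                  _select_per_cluster(detable, clusters, 0.5), mandatory),
    )
    return sets


def _two_medoid(dist: np.ndarray, max_iter: int = 30) -> np.ndarray:
    """Deterministic 2-medoid partition of a precomputed distance matrix.

    Medoids are initialized at the most distant pair, then alternated
    assignment / medoid-update until stable.  Returns 0/1 labels.
    """
    n = dist.shape[0]
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    medoids = [min(i, j), max(i, j)]
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        labels[medoids[0]] = 0
        labels[medoids[1]] = 1
        new = []
        for c in (0, 1):
            members = np.flatnonzero(labels == c)
            within = dist[np.ix_(members, members)].sum(axis=1)
            new.append(members[np.argmin(within)])
        if new == medoids:
            break
        medoids = new
    return labels


def recursive_partition_clusters(dist: np.ndarray, genes: list[str],
                                 silhouette_cut: float = 0.5,
                                 min_size: int = 10,
                                 max_depth: int = 4) -> list[list[str]]:
    """Leaf clusters of a recursive 2-medoid partition over ``genes``.

    At each node a 2-medoid split is proposed; it is accepted only when its
    mean silhouette reaches ``silhouette_cut`` (i.e. the two halves are
    genuinely separated), the node has at least ``min_size`` members, and
    the depth limit has not been reached.  A cohesive (high within-cluster
    correlation) block is therefore never fragmented, while well-separated
    correlation blocks are recovered exactly.
    """

    def rec(idx: np.ndarray, depth: int) -> list[np.ndarray]:
        if len(idx) < max(min_size, 2) or depth >= max_depth:
            return [idx]
        sub = dist[np.ix_(idx, idx)]
        labels = _two_medoid(sub)
        if len(np.unique(labels)) < 2:
            return [idx]
        sil = silhouette_score(sub, labels, metric="precomputed")
        if sil < silhouette_cut:
            return [idx]
        return rec(idx[labels == 0], depth + 1) + \
            rec(idx[labels == 1], depth + 1)

    leaves = rec(np.arange(len(genes)), 0)
    return [[genes[i] for i in leaf] for leaf in leaves]


def build_sets_6_8(detable: pd.DataFrame, expression: CountMatrix,
                   mandatory: list[str]) -> tuple[CandidateFeatureSet, ...]:
    """Sets 6-8: recursive partitioning + top 10% / 20% / 50% per leaf."""
    de = de_genes_for_clustering(detable)
    rules = {6: "recursive-partition top-10% per cluster",
             7: "recursive-partition top-20% per cluster",
             8: "recursive-partition top-50% per cluster"}
    if len(de) < 2:
        warnings.warn("fewer than 2 DE genes at adj_p<0.01; "
                      "falling back to mandatory-only sets")
        return tuple(_finalize(i, rules[i], [], mandatory) for i in (6, 7, 8))
    dist = _correlation_distance(_log_expression(expression, de))
    clusters = recursive_partition_clusters(dist, de)
    return (
        _finalize(6, rules[6],
                  _select_per_cluster(detable, clusters, 0.1), mandatory),
        _finalize(7, rules[7],
                  _select_per_cluster(detable, clusters, 0.2), mandatory),
        _finalize(8, rules[8],
                  _select_per_cluster(detable, clusters, 0.5), mandatory),
    )


def build_all_sets(detable: pd.DataFrame, expression: CountMatrix,
                   mandatory: list[str]) -> list[CandidateFeatureSet]:
    """All eight candidate sets, in set-id order."""
    s12 = build_set_1_2(detable, mandatory)
    s35 = build_sets_3_5(detable, expression, mandatory)
    s68 = build_sets_6_8(detable, expression, mandatory)
    return [*s12, *s35, *s68]


def feature_sets_frame(sets: list[CandidateFeatureSet]) -> pd.DataFrame:
    """Two-column (set_id, gene_id) long-format table for serialization."""
    rows = [(s.set_id, g) for s in sets for g in s.genes]
    return pd.DataFrame(rows, columns=["set_id", "gene_id"])
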