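"""Set-theoretic complementarity between scoring functions.

Each metric defines a *found set*: the benchmark cases for which it
places a near-native (acceptable or better by default) in its top-10
ranked cluster representatives.  For every pair of metrics the module
computes the cardinalities of the union (cases found by either),
symmetric difference (found by exactly one) and relative complements
(found by one but not the other).  Large symmetric differences mark
pairs that succeed on different complexes and are therefore candidates
for synergistic combination; the union shows how far a hypothetical
merger could reach; the (asymmetric) relative complement decomposes the
symmetric difference by direction.

Metrics are grouped by complete-linkage hierarchical clustering with
the symmetric-difference cardinality as the dissimilarity; pairwise
cophenetic distances are the dendrogram merge heights (U-link heights).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .evaluation import CaseResult
from .quality import QualityClass


@dataclass(frozen=True)
class FoundSet:
    """Cases on which a metric succeeds under a fixed (N, quality) criterion."""

    metric: str
    cases: frozenset[str]
    top_n: int = 10
    quality: QualityClass = QualityClass.ACCEPTABLE

    @property
    def criterion(self) -> tuple[int, QualityClass]:
        return (self.top_n, self.quality)


@dataclass(frozen=True)
class PairCardinalities:
    """|A∪B|, |AΔB|, |A∖B|, |B∖A| and |A∩B| for two found sets."""

    union: int
    symmetric_difference: int
    a_minus_b: int
    b_minus_a: int
    intersection: int


def found_set(results: list[CaseResult], metric: str, n: int = 10,
              q: QualityClass = QualityClass.ACCEPTABLE) -> FoundSet:
    cases = frozenset(
        c.case_id for c in results if c.ranked[metric].best_quality(n) >= q
    )
    return FoundSet(metric, cases, n, q)


def pair_cardinalities(a: FoundSet, b: FoundSet) -> PairCardinalities:
    if a.criterion != b.criterion:
        raise ValueError(f"criterion mismatch: {a.criterion} vs {b.criterion}")
    inter = a.cases & b.cases
    return PairCardinalities(
        union=len(a.cases | b.cases),
        symmetric_difference=len(a.cases ^ b.cases),
        a_minus_b=len(a.cases - b.cases),
        b_minus_a=len(b.cases - a.cases),
        intersection=len(inter),
    )


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over metrics with cophenetic distances."""

    labels: list[str]
    linkage: np.ndarray
    cophenetic: pd.DataFrame = field(repr=False)

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cophenetic_distance(self, a: str, b: str) -> float:
        return float(self.cophenetic.loc[a, b])

    def to_newick(self) -> str:
        """Newick text with branch lengths = merge-height increments."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"


def complete_linkage(dissimilarity: pd.DataFrame) -> Dendrogram:
    """Agglomerative complete-linkage clustering of metrics.

    ``dissimilarity`` must be symmetric with a zero diagonal and
    non-negative entries.  Inter-cluster distance is the maximum
    pairwise dissimilarity, so merge heights are non-decreasing and the
    cophenetic distance of a pair is the height of their lowest common
    merge.
    """
    d = dissimilarity.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or list(dissimilarity.index) != list(dissimilarity.columns):
        raise ValueError("dissimilarity must be square with matching labels")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity must be symmetric")
    if np.any(d < 0):
        raise ValueError("dissimilarity must be non-negative")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("dissimilarity diagonal must be zero")
    labels = list(dissimilarity.index)
    condensed = squareform(d, checks=False)
    linkage = hierarchy.linkage(condensed, method="complete")
    coph = squareform(hierarchy.cophenet(linkage))
    coph_df = pd.DataFrame(coph, index=labels, columns=labels)
    return Dendrogram(labels, linkage, coph_df)


@dataclass
class SynergyResult:
    """Ordered pairwise cardinality matrices plus the dendrogram.

    ``symmetric_difference`` and ``union`` are ordered by dendrogram
    leaf order; ``relative_complement`` (entry [i, j] = |A_i \\ A_j|) is
    ordered by individual top-N success rate, descending.
    """

    symmetric_difference: pd.DataFrame
    union: pd.DataFrame
    relative_complement: pd.DataFrame
    dendrogram: Dendrogram
    union_dendrogram: Dendrogram | None
    found_sets: dict[str, FoundSet]


def synergy_matrices(results: list[CaseResult], metrics: list[str],
                     n: int = 10, q: QualityClass = QualityClass.ACCEPTABLE,
                     union_ordering: str = "union") -> SynergyResult:
    """All pairwise set cardinalities, clustered and ordered.

    ``union_ordering='union'`` clusters the union matrix on
    ``max_union - union`` (unions are similarity-like, a clustering
    needs a dissimilarity); ``'symdiff'`` reuses the symmetric-difference
    ordering instead.
    """
    if len(metrics) < 2:
        raise ValueError("need at least two metrics")
    sets = {m: found_set(results, m, n, q) for m in metrics}
    k = len(metrics)
    sym = np.zeros((k, k), dtype=int)
    uni = np.zeros((k, k), dtype=int)
    rel = np.zeros((k, k), dtype=int)
    for i, a in enumerate(metrics):
        uni[i, i] = len(sets[a].cases)
        for j, b in enumerate(metrics):
            if i == j:
                continue
            card = pair_cardinalities(sets[a], sets[b])
            sym[i, j] = card.symmetric_difference
            uni[i, j] = card.union
            rel[i, j] = card.a_minus_b
    sym_df = pd.DataFrame(sym, index=metrics, columns=metrics)
    uni_df = pd.DataFrame(uni, index=metrics, columns=metrics)
    rel_df = pd.DataFrame(rel, index=metrics, columns=metrics)

    dendro = complete_linkage(sym_df)
    order = dendro.leaf_order
    union_dendro = None
    if union_ordering == "union":
        u = uni_df.to_numpy(dtype=float)
        dis = u.max() - u
        np.fill_diagonal(dis, 0.0)
        # symmetrise exactly (floating max introduces no asymmetry, but be safe)
        dis = 0.5 * (dis + dis.T)
        union_dendro = complete_linkage(pd.DataFrame(dis, index=metrics, columns=metrics))
        union_order = union_dendro.leaf_order
    elif union_ordering == "symdiff":
        union_order = order
    else:
        raise ValueError(f"unknown union_ordering {union_ordering!r}")

    success_rate = {m: len(sets[m].cases) for m in metrics}
    rel_order = sorted(metrics, key=lambda m: (-success_rate[m], metrics.index(m)))

    return SynergyResult(
        symmetric_difference=sym_df.loc[order, order],
        union=uni_df.loc[union_order, union_order],
        relative_complement=rel_df.loc[rel_order, rel_order],
        dendrogram=dendro,
        union_dendrogram=union_dendro,
        found_sets=sets,
    )
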