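"""Re-ranking and greedy leader clustering of docking poses.

For each scoring metric the decoys of a case are sorted best-first
(ascending for energies, descending for count-like scores) and swept
through a leader-follower clustering at a 3 A pose-distance threshold:
a decoy joins the first existing cluster whose *leader* is within the
threshold, otherwise it founds a new cluster.  Only the best-scoring
member (the leader) of each cluster is kept, leaving a ranked list of
cluster representatives that all downstream statistics consume.

The pose distance between two decoys is the ligand backbone RMSD after
superposing one decoy's receptor backbone onto the other's (no native
involved); full-complex RMSD is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .quality import QualityClass, kabsch_superpose, rmsd
from .structures import ComplexPartition, DecoySet, Structure, paired_backbone

DEFAULT_CLUSTER_THRESHOLD = 3.0  # A


@dataclass
class RankedDecoys:
    """Decoy ids of one case sorted best-first under one metric."""

    case_id: str
    metric: str
    order: list[str]


@dataclass
class Cluster:
    leader: str
    members: list[str]


@dataclass
class RankedEntry:
    rank: int
    decoy_id: str
    quality: QualityClass
    score: float | None = None


@dataclass
class RankedList:
    """Ordered cluster representatives with quality labels for one (case, metric)."""

    case_id: str
    metric: str
    entries: list[RankedEntry]

    def top(self, n: int) -> list[RankedEntry]:
        return self.entries[:n]

    def best_quality(self, n: int | None = None) -> QualityClass:
        pool = self.entries if n is None else self.entries[:n]
        if not pool:
            return QualityClass.INCORRECT
        return max(e.quality for e in pool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"rank": e.rank, "decoy_id": e.decoy_id, "score": e.score,
              "class": str(e.quality)} for e in self.entries]
        )


def rerank(score_table: pd.DataFrame, metric: str,
           direction: str = "ascending_better", case_id: str = "") -> RankedDecoys:
    """Sort decoys by one metric's scores, best first.

    Missing (NaN) scores are excluded; ties are broken by stable input
    order, so the ranking is deterministic given the table.
    """
    if metric not in score_table.columns:
        raise KeyError(f"metric {metric!r} not in score table")
    scores = score_table[metric].dropna()
    if scores.empty:
        import logging
        logging.getLogger(__name__).warning(
            "all scores missing for metric %s on case %s", metric, case_id)
        return RankedDecoys(case_id, metric, [])
    ascending = direction == "ascending_better"
    order = scores.sort_values(ascending=ascending, kind="mergesort").index.tolist()
    return RankedDecoys(case_id, metric, order)


def pairwise_ligand_rmsd(a: Structure, b: Structure, partition: ComplexPartition) -> float:
    """Ligand backbone RMSD between two poses after receptor superposition."""
    rec_keys = {r.key for r in a.residues if r.chain_id in partition.receptor_chains}
    lig_keys = {r.key for r in a.residues if r.chain_id in partition.ligand_chains}
    rec_a, rec_b = paired_backbone(a, b, rec_keys)
    sup = kabsch_superpose(rec_a, rec_b)
    lig_a, lig_b = paired_backbone(a, b, lig_keys)
    return rmsd(lig_a, sup.apply(lig_b))


def greedy_cluster(ranked: RankedDecoys,
                   pose_distance: Callable[[str, str], float],
                   threshold: float = DEFAULT_CLUSTER_THRESHOLD) -> list[Cluster]:
    """Leader-follower sweep over decoys in rank order.

    Each decoy is assigned to the first existing cluster whose leader is
    within ``threshold``, else it founds a new cluster.  Cluster order
    equals leader score order; every member is within ``threshold`` of
    its leader and leaders are pairwise farther apart than that.
    """
    clusters: list[Cluster] = []
    for decoy_id in ranked.order:
        placed = False
        for cluster in clusters:
            if pose_distance(cluster.leader, decoy_id) <= threshold:
                cluster.members.append(decoy_id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(decoy_id, [decoy_id]))
    return clusters


def representatives(clusters: Sequence[Cluster],
                    quality: Mapping[str, QualityClass],
                    case_id: str = "", metric: str = "",
                    scores: Mapping[str, float] | None = None) -> RankedList:
    """Keep only each cluster's leader, with its quality label attached."""
    entries = []
    for rank, cluster in enumerate(clusters, start=1):
        if cluster.leader not in quality:
            raise KeyError(f"no quality label for decoy {cluster.leader}")
        score = None if scores is None else float(scores[cluster.leader])
        entries.append(RankedEntry(rank, cluster.leader, quality[cluster.leader], score))
    return RankedList(case_id, metric, entries)


class _PoseDistanceCache:
    """Memoised pairwise ligand-RMSD over a fixed decoy set.

    Backbone arrays are extracted once per decoy.  When every decoy's
    fit selection (the receptor backbone) is rigidly congruent to the
    native's — the case for rigid-body decoys — each decoy is aligned to
    the native frame once and pairwise distances reduce to plain RMSDs
    of the aligned coordinates, which is exact.  Otherwise each pair's
    Kabsch fit is computed (and memoised; the distance is symmetric).
    """

    _RIGID_TOL = 1e-6

    def __init__(self, decoy_set: DecoySet, metric: str = "ligand_rmsd"):
        partition = decoy_set.partition
        rec_keys = {r.key for r in decoy_set.native.residues
                    if r.chain_id in partition.receptor_chains}
        lig_keys = {r.key for r in decoy_set.native.residues
                    if r.chain_id in partition.ligand_chains}
        if metric == "ligand_rmsd":
            fit_keys, out_keys = rec_keys, lig_keys
        elif metric == "complex_rmsd":
            fit_keys = rec_keys | lig_keys
            out_keys = fit_keys
        else:
            raise ValueError(f"unknown cluster metric {metric!r}")
        self._fit: dict[str, np.ndarray] = {}
        self._out: dict[str, np.ndarray] = {}
        self._aligned: dict[str, np.ndarray] | None = {}
        native = decoy_set.native
        for decoy_id, structure in decoy_set.decoys:
            fit_n, fit_d = paired_backbone(native, structure, fit_keys)
            out_n, out_d = paired_backbone(native, structure, out_keys)
            del out_n
            self._fit[decoy_id] = fit_d
            self._out[decoy_id] = out_d
            if self._aligned is not None:
                sup = kabsch_superpose(fit_n, fit_d)
                if sup.rmsd < self._RIGID_TOL:
                    self._aligned[decoy_id] = sup.apply(out_d)
                else:
                    self._aligned = None  # flexible receptor: exact pairwise fits
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        if self._aligned is not None:
            return rmsd(self._aligned[a], self._aligned[b])
        key = (a, b) if a < b else (b, a)
        d = self._cache.get(key)
        if d is None:
            sup = kabsch_superpose(self._fit[a], self._fit[b])
            d = rmsd(self._out[a], sup.apply(self._out[b]))
            self._cache[key] = d
        return d


def rank_case(decoy_set: DecoySet, score_table: pd.DataFrame,
              quality_table: pd.DataFrame, metric: str,
              direction: str = "ascending_better",
              threshold: float = DEFAULT_CLUSTER_THRESHOLD,
              cluster_metric: str = "ligand_rmsd") -> RankedList:
    """Full rerank -> cluster -> representatives pass for one (case, metric)."""
    ranked = rerank(score_table, metric, direction, decoy_set.case_id)
    distance = _PoseDistanceCache(decoy_set, cluster_metric)
    clusters = greedy_cluster(ranked, distance, threshold)
    # itemwise: Series.to_dict would unbox the IntEnum labels to plain ints
    quality = {i: v for i, v in quality_table["class"].items()}
    scores = score_table[metric].to_dict()
    return representatives(clusters, quality, decoy_set.case_id, metric, scores)


def write_ranked_list(ranked: RankedList, quality_table: pd.DataFrame, path) -> None:
    """Ranked-list TSV: rank, decoy_id, score, fnat, irmsd, lrmsd, class."""
    frame = ranked.to_frame()
    merged = frame.merge(
        quality_table[["fnat", "irmsd", "lrmsd"]], left_on="decoy_id", right_index=True,
        how="left",
    )
    merged = merged[["rank", "decoy_id", "score", "fnat", "irmsd", "lrmsd", "class"]]
    merged.to_csv(path, sep="\t", index=False, float_format="%.4f")
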