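"""Jaccard similarity of knockout strategies and target clustering.

Two production targets whose best knockout sets overlap heavily can be
produced by closely related strain designs; the membership-based
Jaccard coefficient J = |A ∩ B| / |A ∪ B| quantifies that overlap and
1 − J (a metric) drives agglomerative clustering of the targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard coefficient |a ∩ b| / |a ∪ b| of two knockout sets."""
    sa, sb = frozenset(a), frozenset(b)
    if not sa and not sb:
        raise ValueError("Jaccard coefficient of two empty sets is undefined")
    return len(sa & sb) / len(sa | sb)


@dataclass
class SimilarityMatrix:
    target_ids: list[str]
    values: np.ndarray  # symmetric, in [0, 1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.target_ids, columns=self.target_ids)


def similarity_matrix(sets: Mapping[str, Iterable[str]]) -> SimilarityMatrix:
    """Pairwise Jaccard similarity over targets with nonempty knockout sets."""
    items = sorted((t, frozenset(s)) for t, s in sets.items() if frozenset(s))
    if not items:
        raise ValueError("no targets with nonempty knockout sets")
    ids = [t for t, _ in items]
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = jaccard(items[i][1], items[j][1])
    return SimilarityMatrix(target_ids=ids, values=values)


@dataclass
class ClusteringResult:
    target_ids: list[str]
    linkage: np.ndarray
    newick: str
    labels: dict[str, int] | None = None
    similarity: SimilarityMatrix | None = None


def _to_newick(node: hierarchy.ClusterNode, labels: list[str]) -> str:
    def rec(n: hierarchy.ClusterNode, parent_dist: float) -> str:
        length = parent_dist - n.dist
        if n.is_leaf():
            return f"{labels[n.id]}:{length:.6g}"
        left = rec(n.get_left(), n.dist)
        right = rec(n.get_right(), n.dist)
        return f"({left},{right}):{length:.6g}"

    if node.is_leaf():
        return f"{labels[node.id]}:0;"
    left = rec(node.get_left(), node.dist)
    right = rec(node.get_right(), node.dist)
    return f"({left},{right});"


def cluster_targets(
    sets: Mapping[str, Iterable[str]],
    method: str = "average",
    cut_height: float | None = None,
) -> ClusteringResult:
    """Agglomerative clustering of targets on Jaccard distance 1 − J.

    ``method`` is the linkage rule ("single", "complete" or "average";
    default UPGMA).  When ``cut_height`` is given, flat cluster labels
    at that distance threshold are included.  Deterministic: targets are
    processed in sorted id order.
    """
    if method not in ("single", "complete", "average"):
        raise ValueError(f"unsupported linkage method {method!r}")
    sim = similarity_matrix(sets)
    if len(sim.target_ids) < 2:
        raise ValueError("need at least two targets with nonempty knockout sets")
    dist = 1.0 - sim.values
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method=method)
    tree = hierarchy.to_tree(linkage)
    newick = _to_newick(tree, sim.target_ids)
    labels = None
    if cut_height is not None:
        flat = hierarchy.fcluster(linkage, t=cut_height, criterion="distance")
        labels = {t: int(c) for t, c in zip(sim.target_ids, flat)}
    return ClusteringResult(
        target_ids=sim.target_ids, linkage=linkage, newick=newick,
        labels=labels, similarity=sim,
    )


def shared_units(
    sets: Mapping[str, Iterable[str]],
    labels: Mapping[str, int],
    threshold: float = 0.9,
) -> dict[int, list[str]]:
    """Knockout units present in more than ``threshold`` of a cluster's sets.

    Mirrors the per-cluster "shared knockout" report: a unit counts as
    shared within a cluster when it appears in > 90% (by default) of
    the member targets' knockout sets.
    """
    clusters: dict[int, list[frozenset[str]]] = {}
    for target, label in labels.items():
        clusters.setdefault(label, []).append(frozenset(sets[target]))
    report: dict[int, list[str]] = {}
    for label, members in sorted(clusters.items()):
        counts: dict[str, int] = {}
        for s in members:
            for unit in s:
                counts[unit] = counts.get(unit, 0) + 1
        report[label] = sorted(
            u for u, c in counts.items() if c / len(members) > threshold
        )
    return report
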