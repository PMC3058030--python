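"""Co-occurrence clustering of significant proteins.

Significant proteins for a metal are clustered by their fraction
co-occurrence profiles: Euclidean distances between Boolean presence
vectors, Ward (variance-minimizing) linkage, and a dynamic hybrid tree cut.
Each resulting cluster is expected to contain at least one distinct
metalloprotein in order to explain the metal-peak data, so the number of
clusters is the framework's estimate of the metal's metalloprotein count.

The hybrid cut works in three steps: (1) a static cut at
``cut_height_fraction`` times the maximum merge height separates the
top-level branches; (2) branches are recursively split where both children
reach ``min_cluster_size`` and the merge is separated from its children by a
relative height gap controlled by ``deep_split`` (0 = least, 4 = most
splitting); (3) leftover branches smaller than ``min_cluster_size`` are left
unassigned (label 0).

A cluster's *core region* is the set of fractions in which at least half of
the cluster's proteins were observed; well-separated clusters have nearly
disjoint cores that coincide with metal-peak regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import ClusterNode, linkage, to_tree

from .peaks import PeakSet

__all__ = [
    "ClusterReport",
    "cluster_proteins",
    "compute_cores",
    "cluster_covered_peaks",
    "build_report",
    "predict_metalloprotein_count",
]


@dataclass
class ClusterReport:
    """Per-metal clustering outcome."""

    metal: str
    assignments: dict[str, int]  # protein_id -> label (0 = unassigned)
    n_clusters: int
    core_fractions: dict[int, set[str]] = field(default_factory=dict)
    pairwise_core_overlap: dict[tuple[int, int], float] = field(default_factory=dict)
    covered_peaks: dict[int, set[str]] = field(default_factory=dict)


def _gap_threshold(deep_split: int) -> float:
    # deep_split 0..4 maps to a relative-gap requirement of 0.4 .. 0.0;
    # higher deep_split splits branches more aggressively
    return (4 - deep_split) / 10.0


def _chain_branches(node: ClusterNode, threshold: float) -> list[ClusterNode]:
    """Sub-branches hanging below the chain of near-top-height merges.

    Merges whose height is within the gap tolerance of the entry node are
    treated as one multi-way split (Ward trees render a k-way separation as
    a ladder of similar-height pairwise merges), so the branches returned
    are the subtrees below that ladder.
    """
    if not node.is_leaf() and node.dist >= threshold:
        return _chain_branches(node.get_left(), threshold) + _chain_branches(
            node.get_right(), threshold
        )
    return [node]


def _cut_tree(
    node: ClusterNode,
    static_height: float,
    min_cluster_size: int,
    gap_frac: float,
) -> list[list[int]]:
    """Leaves of the branches where cutting stops, top-down."""
    if node.is_leaf() or node.dist == 0:
        return [node.pre_order(lambda leaf: leaf.id)]
    left, right = node.get_left(), node.get_right()
    if node.dist > static_height:
        return _cut_tree(left, static_height, min_cluster_size, gap_frac) + _cut_tree(
            right, static_height, min_cluster_size, gap_frac
        )
    # branch-gap criterion: the merges within gap_frac of this node's height
    # form one multi-way split; it is accepted when it separates at least two
    # branches of viable size, and each branch is then evaluated recursively
    threshold = (1.0 - gap_frac) * node.dist
    branches = _chain_branches(left, threshold) + _chain_branches(right, threshold)
    viable = [b for b in branches if b.get_count() >= min_cluster_size]
    if len(viable) >= 2:
        out: list[list[int]] = []
        for branch in branches:
            out.extend(_cut_tree(branch, static_height, min_cluster_size, gap_frac))
        return out
    return [node.pre_order(lambda leaf: leaf.id)]


def cluster_proteins(
    matrix: pd.DataFrame,
    metal: str = "",
    min_cluster_size: int = 3,
    deep_split: int = 2,
    cut_height_fraction: float = 0.99,
) -> tuple[np.ndarray, ClusterReport]:
    """Ward/Euclidean clustering of a Boolean presence matrix with hybrid cut.

    Rows are canonically re-ordered by protein ID before distances are
    computed, so the result is independent of input row order.  Returns the
    linkage matrix and a :class:`ClusterReport` skeleton (assignments and
    cluster count only; cores are filled in by :func:`compute_cores`).
    """
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    if len(matrix) < 2:
        raise ValueError(f"clustering needs >= 2 proteins, got {len(matrix)}")
    matrix = matrix.sort_index(kind="mergesort")
    X = matrix.to_numpy(dtype=float)
    Z = linkage(X, method="ward", metric="euclidean")
    root = to_tree(Z)
    static_height = cut_height_fraction * float(Z[:, 2].max())
    branches = _cut_tree(root, static_height, min_cluster_size, _gap_threshold(deep_split))
    # canonical labels: clusters ordered by their smallest row index
    branches.sort(key=min)
    assignments: dict[str, int] = {}
    label = 0
    for leaves in branches:
        if len(leaves) >= min_cluster_size:
            label += 1
            this = label
        else:
            this = 0
        for i in leaves:
            assignments[matrix.index[i]] = this
    report = ClusterReport(metal=metal, assignments=assignments, n_clusters=label)
    return Z, report


def compute_cores(
    matrix: pd.DataFrame, assignments: dict[str, int]
) -> tuple[dict[int, set[str]], dict[tuple[int, int], float]]:
    """Core fractions (>= 50% of cluster proteins present) and core overlaps.

    The boundary is inclusive: a fraction containing exactly half the
    cluster's proteins is core.  Overlap between two clusters is the Jaccard
    index of their core fraction sets.
    """
    labels = sorted({v for v in assignments.values() if v > 0})
    cores: dict[int, set[str]] = {}
    for lab in labels:
        members = [p for p, v in assignments.items() if v == lab]
        frac_presence = matrix.loc[members].mean(axis=0)
        cores[lab] = set(frac_presence.index[frac_presence >= 0.5])
    overlaps: dict[tuple[int, int], float] = {}
    for c1, c2 in combinations(labels, 2):
        union = cores[c1] | cores[c2]
        overlaps[(c1, c2)] = len(cores[c1] & cores[c2]) / len(union) if union else 0.0
    return cores, overlaps


def cluster_covered_peaks(
    matrix: pd.DataFrame, assignments: dict[str, int], peaks: PeakSet
) -> dict[int, set[str]]:
    """Peaks touched (>= 1 shared fraction) by each cluster's proteins."""
    out: dict[int, set[str]] = {}
    for lab in sorted({v for v in assignments.values() if v > 0}):
        members = [p for p, v in assignments.items() if v == lab]
        present = set(matrix.columns[matrix.loc[members].any(axis=0)])
        out[lab] = {r.peak_id for r in peaks.regions if present & set(r.fraction_ids)}
    return out


def build_report(
    matrix: pd.DataFrame,
    metal: str,
    peaks: PeakSet | None = None,
    min_cluster_size: int = 3,
    deep_split: int = 2,
    cut_height_fraction: float = 0.99,
) -> tuple[np.ndarray, ClusterReport]:
    """Cluster, compute cores/overlaps (and peak coverage when peaks given)."""
    Z, report = cluster_proteins(
        matrix,
        metal=metal,
        min_cluster_size=min_cluster_size,
        deep_split=deep_split,
        cut_height_fraction=cut_height_fraction,
    )
    report.core_fractions, report.pairwise_core_overlap = compute_cores(matrix, report.assignments)
    if peaks is not None:
        report.covered_peaks = cluster_covered_peaks(matrix, report.assignments, peaks)
    return Z, report


def predict_metalloprotein_count(report: ClusterReport) -> int:
    """Estimated number of distinct metalloproteins for the metal."""
    return report.n_clusters
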