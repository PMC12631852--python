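"""Multi-anchor construction between scATAC and scRNA cells.

High-weight anchors are mutual nearest neighbours (MNN) across the two
modalities in the current joint embedding.  scATAC cells without a
direct MNN partner can still be anchored with low weight when (1) at
least one of their peak-space graph neighbours holds a high-weight
anchor and (2) they sit closer to the centroid of the RNA cluster their
neighbours point at than to any other cluster centroid.  Each anchored
ATAC cell is thereby assigned to one RNA cluster; those assignments
define the anchored groups used by the GAS loss once training leaves
the warm-up phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import PeakGraph, knn_indices

__all__ = ["AnchorSet", "ClusterSummary", "compute_cluster_summary", "find_mnn_anchors", "extend_low_anchors", "build_anchor_set"]


@dataclass
class AnchorSet:
    """High/low-weight ATAC->RNA pairings and per-cell cluster assignments."""

    high: list  # (atac_index, rna_index)
    low: list
    atac_cluster_assignment: dict  # atac_index -> RNA cluster index
    epoch_stamp: int = -1

    def __post_init__(self):
        h = {i for i, _ in self.high}
        l = {i for i, _ in self.low}
        if h & l:
            raise ValueError(f"cells in both anchor tiers: {sorted(h & l)[:10]}")

    @property
    def high_map(self) -> dict:
        return dict(self.high)

    @property
    def low_map(self) -> dict:
        return dict(self.low)

    def to_records(self):
        rec = [(i, j, "high", self.epoch_stamp) for i, j in self.high]
        rec += [(i, j, "low", self.epoch_stamp) for i, j in self.low]
        return rec


@dataclass
class ClusterSummary:
    """Per-class centroids of the RNA embedding and inter-cluster distances.

    ``centroids[k]`` is the arithmetic mean embedding of RNA cells with
    class code k; ``pair_dist[i, j]`` is the mean Euclidean distance over
    all cross pairs between clusters i and j.
    """

    centroids: np.ndarray  # K x d
    class_sizes: np.ndarray
    pair_dist: np.ndarray  # K x K, symmetric, zero diagonal

    def __post_init__(self):
        if not np.allclose(self.pair_dist, self.pair_dist.T):
            raise ValueError("pairwise distance matrix must be symmetric")
        if not np.allclose(np.diag(self.pair_dist), 0.0):
            raise ValueError("pairwise distance diagonal must be zero")


def compute_cluster_summary(E_r: np.ndarray, label_codes: np.ndarray,
                            K: int | None = None) -> ClusterSummary:
    """Centroids and mean cross-pair distances per RNA class."""
    E_r = np.asarray(E_r, dtype=np.float64)
    label_codes = np.asarray(label_codes, dtype=np.intp)
    if K is None:
        K = int(label_codes.max()) + 1
    groups = []
    for k in range(K):
        idx = np.flatnonzero(label_codes == k)
        if idx.size == 0:
            raise ValueError(f"class {k} has no cells in the embedding")
        groups.append(E_r[idx])
    centroids = np.stack([g.mean(axis=0) for g in groups])
    sizes = np.array([len(g) for g in groups])
    D = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            diff = groups[i][:, None, :] - groups[j][None, :, :]
            D[i, j] = D[j, i] = np.sqrt((diff**2).sum(axis=2)).mean()
    return ClusterSummary(centroids, sizes, D)


def find_mnn_anchors(E_a: np.ndarray, E_r: np.ndarray, k_mnn: int = 10) -> list:
    """Mutual-nearest-neighbour (high-weight) anchors in embedding space.

    A pair (i, j) qualifies when j is among the k_mnn nearest RNA cells
    of ATAC cell i AND i is among the k_mnn nearest ATAC cells of RNA
    cell j.  When an ATAC cell has several mutual partners only the
    nearest is kept (ties to the lowest RNA index), so the result is a
    map ATAC -> RNA.
    """
    E_a = np.asarray(E_a, dtype=np.float64)
    E_r = np.asarray(E_r, dtype=np.float64)
    n2, n1 = E_a.shape[0], E_r.shape[0]
    if k_mnn >= min(n1, n2):
        raise ValueError(f"k_mnn={k_mnn} must be below min(n1, n2)={min(n1, n2)}")
    a2r = knn_indices(E_a, E_r, k_mnn)  # n2 x k, ordered nearest first
    r2a = knn_indices(E_r, E_a, k_mnn)
    rna_sees = [set(row.tolist()) for row in r2a]
    anchors = []
    for i in range(n2):
        for j in a2r[i]:  # nearest-first, so the first mutual hit wins
            if i in rna_sees[j]:
                anchors.append((i, int(j)))
                break
    return anchors


def extend_low_anchors(high: list, peak_graph: PeakGraph, E_a: np.ndarray,
                       E_r: np.ndarray, summary: ClusterSummary,
                       rna_label_codes: np.ndarray):
    """Low-weight anchors for ATAC cells adjacent to anchored cells.

    For each unanchored cell i the anchored graph neighbours vote (via
    their partners' RNA labels) for a target cluster C*; ties go to the
    cluster whose centroid is nearest to i.  The cell is anchored iff it
    is strictly nearest to C*'s centroid among all centroids; its RNA
    partner is the anchor of the nearest voting neighbour.  Returns the
    low anchor list and the cluster assignment for every anchored cell
    (high-weight cells inherit their partner's label).
    """
    E_a = np.asarray(E_a, dtype=np.float64)
    rna_label_codes = np.asarray(rna_label_codes, dtype=np.intp)
    high_map = dict(high)
    assignment = {i: int(rna_label_codes[j]) for i, j in high_map.items()}
    low = []
    cent = summary.centroids
    for i in range(E_a.shape[0]):
        if i in high_map:
            continue
        voters = [j for j in peak_graph.neighbors_of(i) if j in high_map]
        if not voters:
            continue  # condition (1) fails
        votes = np.array([assignment[j] for j in voters])
        dists = np.sqrt(((cent - E_a[i]) ** 2).sum(axis=1))
        counts = np.bincount(votes, minlength=cent.shape[0])
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        c_star = int(tied[np.argmin(dists[tied])])  # nearest centroid among ties
        if not np.all(dists[c_star] < np.delete(dists, c_star)):
            continue  # condition (2): strictly nearest to C*
        voters_c = [j for j in voters if assignment[j] == c_star]
        nd = [np.linalg.norm(E_a[i] - E_a[j]) for j in voters_c]
        best = voters_c[int(np.argmin(nd))]
        low.append((i, high_map[best]))
        assignment[i] = c_star
    return low, assignment


def build_anchor_set(E_a, E_r, peak_graph, rna_label_codes, k_mnn=10, K=None,
                     epoch=-1):
    """Full anchor refresh: MNN anchors, centroid summary, low extension."""
    summary = compute_cluster_summary(E_r, rna_label_codes, K=K)
    high = find_mnn_anchors(E_a, E_r, k_mnn=k_mnn)
    low, assignment = extend_low_anchors(
        high, peak_graph, E_a, E_r, summary, rna_label_codes
    )
    return AnchorSet(high, low, assignment, epoch_stamp=epoch), summary
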