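"""Normalisation, peak-space PCA and the scATAC cell graph.

Expression and GAS counts are library-size scaled and log1p transformed.
The peak matrix is binarised and TF-IDF weighted (the standard scATAC
recipe) before PCA.  The peak graph stores, for every scATAC cell, the
set N(i) = {i} U {its k nearest neighbours in the PCA peak space}; this
graph defines the neighbourhood cohesion term of the GAS loss and the
candidate pool for low-weight anchors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.spatial.distance
from sklearn.decomposition import PCA

from .data_model import InputError, ModalityDataset

__all__ = ["PeakGraph", "normalize_counts", "tfidf", "pca_reduce", "build_peak_graph", "knn_indices"]


@dataclass
class PeakGraph:
    """Per-cell neighbour sets in the peak space.

    ``neighbor_sets[i]`` always contains ``i`` itself plus ``k_graph``
    neighbours, so each set has ``k_graph + 1`` members.
    """

    neighbor_sets: list
    k_graph: int

    def __post_init__(self):
        n = len(self.neighbor_sets)
        for i, ns in enumerate(self.neighbor_sets):
            if i not in ns:
                raise ValueError(f"cell {i} missing from its own neighbour set")
            if len(ns) != self.k_graph + 1:
                raise ValueError(
                    f"N({i}) has {len(ns)} members, expected {self.k_graph + 1}"
                )
            if min(ns) < 0 or max(ns) >= n:
                raise ValueError(f"N({i}) has out-of-range indices")

    def neighbors_of(self, i: int) -> np.ndarray:
        """Neighbours of cell ``i`` excluding ``i`` itself."""
        return np.array([j for j in self.neighbor_sets[i] if j != i], dtype=np.intp)

    def to_edge_list(self):
        return [(i, j) for i, ns in enumerate(self.neighbor_sets) for j in sorted(ns) if j != i]


def normalize_counts(ds: ModalityDataset, target_sum: float = 1e4) -> ModalityDataset:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    All-zero cells are left at zero (with a warning); the zero pattern of
    the matrix is preserved exactly.
    """
    if ds.modality_tag not in ("rna", "gas"):
        raise InputError(f"normalize_counts expects rna/gas, got {ds.modality_tag}")
    if np.any(ds.matrix < 0):
        raise InputError("negative entries in count matrix")
    sums = ds.matrix.sum(axis=1)
    zero = sums == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero cells left unnormalised")
    scale = np.where(zero, 1.0, target_sum / np.where(zero, 1.0, sums))
    out = np.log1p(ds.matrix * scale[:, None])
    return ModalityDataset(out, ds.cell_ids, ds.feature_ids, ds.modality_tag, ds.labels)


def tfidf(matrix: np.ndarray) -> np.ndarray:
    """Binarise a peak-count matrix and apply TF-IDF weighting.

    TF is per-cell frequency of accessible peaks; IDF is
    ``log(1 + n_cells / n_cells_with_peak)``.
    """
    binary = (np.asarray(matrix) > 0).astype(np.float64)
    row = binary.sum(axis=1)
    tf = binary / np.where(row == 0, 1.0, row)[:, None]
    col = binary.sum(axis=0)
    idf = np.log1p(binary.shape[0] / np.where(col == 0, 1.0, col))
    return tf * idf[None, :]


def pca_reduce(peaks: ModalityDataset, m: int = 50, seed: int = 0,
               apply_tfidf: bool = True) -> ModalityDataset:
    """Project the (TF-IDF transformed) peak matrix to ``m`` PCs.

    Components are ordered by decreasing explained variance and the sign
    convention is fixed by the solver seed, so the output is deterministic
    for a fixed seed.
    """
    n, p = peaks.matrix.shape
    if m >= min(n, p):
        raise InputError(f"m={m} must be below min(cells, features)={min(n, p)}")
    x = tfidf(peaks.matrix) if apply_tfidf else peaks.matrix
    pca = PCA(n_components=m, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(x)
    return ModalityDataset(
        coords, peaks.cell_ids, [f"PC{j + 1}" for j in range(m)], "peak_pca",
        peaks.labels,
    )


def knn_indices(query: np.ndarray, ref: np.ndarray, k: int,
                exclude_self: bool = False, chunk: int = 1024) -> np.ndarray:
    """Exact k nearest neighbours of each query row among ``ref`` rows.

    Euclidean distance; ties broken by lower reference index (stable
    sort).  ``exclude_self`` skips index i for query row i (for
    self-search).  Returns an (n_query, k) integer array ordered from
    nearest to farthest.
    """
    query = np.asarray(query, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    n = query.shape[0]
    out = np.empty((n, k), dtype=np.intp)
    direct = n * ref.shape[0] <= 8_000_000  # direct differences: no cancellation
    ref_sq = None if direct else (ref**2).sum(axis=1)
    for a in range(0, n, chunk):
        b = min(a + chunk, n)
        q = query[a:b]
        if direct:
            d2 = scipy.spatial.distance.cdist(q, ref, "sqeuclidean")
        else:
            d2 = (q**2).sum(axis=1)[:, None] - 2.0 * q @ ref.T + ref_sq[None, :]
            d2 = np.maximum(d2, 0.0)
        # round away float jitter among exactly-tied distances so the
        # stable sort's index tie-break is honoured
        d2 = d2.round(decimals=9)
        if exclude_self:
            rows = np.arange(a, b)
            d2[np.arange(b - a), rows] = np.inf
        order = np.argsort(d2, axis=1, kind="stable")
        out[a:b] = order[:, :k]
    return out


def build_peak_graph(xp: ModalityDataset, k_graph: int = 15) -> PeakGraph:
    """Neighbour sets N(i) over the peak-space PCA coordinates."""
    if k_graph <= 0:
        raise InputError(f"k_graph must be positive, got {k_graph}")
    n = xp.n_cells
    if k_graph >= n:
        raise InputError(f"k_graph={k_graph} must be below the cell count {n}")
    nn = knn_indices(xp.matrix, xp.matrix, k_graph, exclude_self=True)
    sets = [frozenset([i]) | frozenset(nn[i].tolist()) for i in range(n)]
    return PeakGraph([set(s) for s in sets], k_graph)
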