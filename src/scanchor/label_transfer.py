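"""Final annotation of ATAC cells in the joint embedding.

Two classifiers vote: a KNN score (fraction of the k nearest RNA cells
carrying each label) and a Euclidean centroid score exp(-distance to
each RNA cluster centroid).  The centroid term counterbalances the KNN
classifier's bias toward abundant cell types, which is what rescues
rare clusters.  The combination s1*K_score + s2*E_score is a score, not
a probability simplex, and is reported unnormalised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import LabelCodebook
from .network import predict_label
from .preprocess import knn_indices

__all__ = ["TransferResult", "knn_score", "euclid_score", "combine_and_assign", "transfer_labels"]


@dataclass
class TransferResult:
    """Per-ATAC-cell class scores and predicted labels."""

    P: np.ndarray  # n2 x K combined score
    predicted_codes: np.ndarray
    K_score: np.ndarray
    E_score: np.ndarray
    k_nn: int
    s1: float
    s2: float

    def predicted_labels(self, codebook: LabelCodebook) -> np.ndarray:
        return codebook.decode(self.predicted_codes)


def knn_score(E_a: np.ndarray, E_r: np.ndarray, rna_label_codes: np.ndarray,
              k_nn: int = 30, K: int | None = None) -> np.ndarray:
    """Fraction of each ATAC cell's k nearest RNA cells per class.

    Euclidean distances in the joint embedding; distance ties resolved
    to the lower RNA index.  Rows sum to 1.
    """
    if k_nn <= 0:
        raise ValueError(f"k_nn must be positive, got {k_nn}")
    E_r = np.asarray(E_r)
    if k_nn > E_r.shape[0]:
        raise ValueError(f"k_nn={k_nn} exceeds the RNA cell count {E_r.shape[0]}")
    rna_label_codes = np.asarray(rna_label_codes, dtype=np.intp)
    if K is None:
        K = int(rna_label_codes.max()) + 1
    nn = knn_indices(E_a, E_r, k_nn)
    votes = rna_label_codes[nn]  # n2 x k_nn
    out = np.zeros((nn.shape[0], K))
    for k in range(K):
        out[:, k] = (votes == k).sum(axis=1)
    return out / k_nn


def euclid_score(E_a: np.ndarray, centroids: np.ndarray,
                 temperature: float = 1.0) -> np.ndarray:
    """exp(-distance / temperature) to each RNA cluster centroid."""
    E_a = np.asarray(E_a, dtype=np.float64)
    centroids = np.asarray(centroids, dtype=np.float64)
    diff = E_a[:, None, :] - centroids[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    return np.exp(-dist / temperature)


def combine_and_assign(K_score: np.ndarray, E_score: np.ndarray,
                       s1: float = 0.2, s2: float = 0.8,
                       k_nn: int = 30) -> TransferResult:
    """P = s1*K_score + s2*E_score; labels by row argmax (ties -> lowest)."""
    if s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
        raise ValueError(f"invalid score weights s1={s1}, s2={s2}")
    K_score = np.asarray(K_score, dtype=np.float64)
    E_score = np.asarray(E_score, dtype=np.float64)
    if K_score.shape != E_score.shape:
        raise ValueError("score matrices must have the same shape")
    P = s1 * K_score + s2 * E_score
    return TransferResult(
        P=P, predicted_codes=predict_label(P), K_score=K_score,
        E_score=E_score, k_nn=k_nn, s1=s1, s2=s2,
    )


def transfer_labels(E_a, E_r, rna_label_codes, centroids, k_nn=30,
                    s1=0.2, s2=0.8, temperature=1.0) -> TransferResult:
    """KNN + centroid scoring in one call."""
    K = centroids.shape[0]
    ks = knn_score(E_a, E_r, rna_label_codes, k_nn=k_nn, K=K)
    es = euclid_score(E_a, centroids, temperature=temperature)
    return combine_and_assign(ks, es, s1=s1, s2=s2, k_nn=k_nn)
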