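"""The training objective: seven minibatch loss terms and their weights.

The objective shapes a joint embedding in which (a) RNA cell clusters are
compact, mutually separated, decorrelated across embedding features and
centred near zero; (b) ATAC cells are cohesive over their peak-space
neighbourhoods (before anchors exist) or over their anchored clusters
(afterwards); (c) anchored ATAC cells are pulled onto their RNA partners
and their partners' cluster centroids, with lower force for inferred
(low-weight) anchors; (d) the two modalities share first and second
moments; and (e) the prediction head classifies RNA cells correctly.

Conventions fixed here (the printed formulas leave them open):
  * sums over unequal index pairs (cluster pairs, covariance entries) run
    over ordered pairs, so each unordered pair counts twice;
  * the covariance and global-mean penalties use absolute values, keeping
    every term bounded below;
  * standard deviations are population (divide by the count);
  * inverted terms carry an eps = 1e-8 guard against constant embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, concat, gather_rows
from .network import predict_label

__all__ = [
    "EPS", "LossWeights", "compute_weight_schedule", "loss_rna", "loss_gas",
    "loss_high", "loss_low", "loss_batch", "loss_cf", "total_loss",
]

EPS = 1e-8


def _round_half_away(x: float) -> float:
    return float(np.floor(x + 0.5)) if x >= 0 else float(-np.floor(-x + 0.5))


def compute_weight_schedule(K: int, rare: float):
    """Cluster-count / rare-fraction driven weights of the moment terms.

    w1 = round(K/10) * (rare + 0.01);  w2 = round(K/10);  w3 = 2/K,
    with round = nearest integer, halves away from zero.
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    if not 0.0 <= rare <= 1.0:
        raise ValueError(f"rare must be in [0, 1], got {rare}")
    w2 = _round_half_away(K / 10.0)
    w1 = w2 * (rare + 0.01)
    w3 = 2.0 / K
    return w1, w2, w3


@dataclass
class LossWeights:
    """All objective weights; w1-w3 follow the (K, rare) schedule."""

    w1: float = 0.0
    w2: float = 0.0
    w3: float = 0.0
    w4: float = 1.5
    w5: float = 0.8
    w6: float = 0.01
    s1: float = 0.2
    s2: float = 0.8
    K: int = 2
    rare: float = 0.0

    @classmethod
    def from_schedule(cls, K: int, rare: float, **overrides) -> "LossWeights":
        w1, w2, w3 = compute_weight_schedule(K, rare)
        return cls(w1=w1, w2=w2, w3=w3, K=K, rare=rare, **overrides)


@dataclass
class Minibatch:
    """Paired half-batches: n labelled RNA cells and n ATAC cells."""

    rna_idx: np.ndarray
    atac_idx: np.ndarray
    rna_labels: np.ndarray = field(default=None)

    def __post_init__(self):
        self.rna_idx = np.asarray(self.rna_idx, dtype=np.intp)
        self.atac_idx = np.asarray(self.atac_idx, dtype=np.intp)
        if len(self.rna_idx) != len(self.atac_idx):
            raise ValueError("RNA and ATAC half-batches must be equal-sized")

    @property
    def n(self) -> int:
        return len(self.rna_idx)


# ----------------------------------------------------------------------
# building blocks


def _mean_sigma_inv(E: Tensor, w1: float) -> Tensor:
    """(1 - w1) * (mean feature std)^-1 with the eps guard."""
    sigma = E.std(axis=0)
    return (1.0 - w1) * (sigma.mean() + EPS) ** -1


def _cov_offdiag(E: Tensor, w2: float) -> Tensor:
    """w2 * sum of |off-diagonal| covariance entries / d^2 (population)."""
    n, d = E.shape
    centred = E - E.mean(axis=0, keepdims=True)
    cov = (centred.T @ centred) / n
    mask = 1.0 - np.eye(d)
    return w2 * (cov.abs() * mask).sum() / (d * d)


def _mean_anchor(E: Tensor, w3: float) -> Tensor:
    """w3 * |sum of all entries| / (n*d): pins the global mean near zero."""
    n, d = E.shape
    return w3 * E.sum().abs() / (n * d)


def _group_sigma_sum(E: Tensor, groups) -> Tensor:
    """Sum over groups of the per-feature std summed over features."""
    total = None
    for idx in groups:
        s = E.take_rows(np.asarray(idx, dtype=np.intp)).std(axis=0).sum()
        total = s if total is None else total + s
    return total


def _pair_distance_mean(A: Tensor, B: Tensor) -> Tensor:
    """Mean Euclidean distance over all cross pairs of rows of A and B."""
    p, d = A.shape
    q = B.shape[0]
    diff = A.reshape(p, 1, d) - B.reshape(1, q, d)
    sq = (diff**2).sum(axis=2)
    return ((sq + 1e-18).sqrt()).mean()


def _separation(E: Tensor, groups, w1: float, denom_groups: int) -> Tensor:
    """-w1 * sum over ordered group pairs of mean cross distance / m^2."""
    if len(groups) < 2 or w1 == 0.0:
        return Tensor(0.0)
    subs = [E.take_rows(np.asarray(g, dtype=np.intp)) for g in groups]
    total = None
    for i in range(len(subs)):
        for j in range(len(subs)):
            if i == j:
                continue
            dij = _pair_distance_mean(subs[i], subs[j])
            total = dij if total is None else total + dij
    return (-w1) * total / (denom_groups**2)


# ----------------------------------------------------------------------
# the seven terms


def loss_rna(E_r, label_codes, w1: float, w2: float, w3: float) -> Tensor:
    """RNA embedding loss: cluster separation, cohesion, decorrelation.

    Terms: -w1 * ordered-pair mean inter-cluster distance / |C_B|^2
    + (1-w1) * (mean feature std)^-1
    + mean over clusters of mean within-cluster feature std
    + w2 * |off-diag covariance| / d^2 + w3 * |global sum| / (n*d).
    """
    E_r = as_tensor(E_r)
    label_codes = np.asarray(label_codes, dtype=np.intp)
    n, d = E_r.shape
    present = np.unique(label_codes)
    groups = [np.flatnonzero(label_codes == k) for k in present]
    m = len(groups)
    loss = _separation(E_r, groups, w1, m)
    loss = loss + _mean_sigma_inv(E_r, w1)
    loss = loss + _group_sigma_sum(E_r, groups) / (m * d)
    loss = loss + _cov_offdiag(E_r, w2)
    loss = loss + _mean_anchor(E_r, w3)
    return loss


def loss_gas(E_a, w1: float, w2: float, w3: float, mode: str = "graph",
             neighbor_values: np.ndarray | None = None,
             anchored_groups=None) -> Tensor:
    """ATAC embedding loss in graph or anchored mode.

    Graph mode keeps each cell close to its peak-space neighbourhood
    N(i): the cohesion term is the mean over cells of the mean feature
    std across N(i)'s embeddings (``neighbor_values`` holds the
    neighbours' embedding rows, cells x k x d, treated as constants; the
    cell's own differentiable row is prepended).  Anchored mode mirrors
    the RNA loss with clusters replaced by the anchored groups C'_i
    (lists of batch-local indices); unanchored cells enter only the
    batch-global terms.
    """
    E_a = as_tensor(E_a)
    n, d = E_a.shape
    loss = _mean_sigma_inv(E_a, w1)
    if mode == "graph":
        if neighbor_values is not None and neighbor_values.shape[1] > 0:
            k = neighbor_values.shape[1]
            stacked = concat(
                [E_a.reshape(n, 1, d), Tensor(neighbor_values)], axis=1
            )
            loss = loss + stacked.std(axis=1).sum() / (n * d)
        # N(i) = {i}: per-cell std is zero, the cohesion term vanishes
    elif mode == "anchored":
        groups = [np.asarray(g, dtype=np.intp) for g in (anchored_groups or [])
                  if len(g) > 0]
        if groups:
            m = len(groups)
            loss = loss + _separation(E_a, groups, w1, m)
            loss = loss + _group_sigma_sum(E_a, groups) / (m * d)
    else:
        raise ValueError(f"mode must be 'graph' or 'anchored', got {mode!r}")
    loss = loss + _cov_offdiag(E_a, w2)
    loss = loss + _mean_anchor(E_a, w3)
    return loss


def _anchor_pull(E_a: Tensor, atac_idx, partner_rows, centroid_rows,
                 n: int, w4: float) -> Tensor:
    atac_idx = np.asarray(atac_idx, dtype=np.intp)
    if atac_idx.size == 0:
        return Tensor(0.0)
    d = E_a.shape[1]
    rows = E_a.take_rows(atac_idx)
    cell_term = (rows - as_tensor(partner_rows)).abs().sum() / (n * d)
    cluster_term = (rows - as_tensor(centroid_rows)).abs().sum() / (n * d)
    return cell_term + w4 * cluster_term


def loss_high(E_a, atac_idx, partner_rows, centroid_rows, n: int,
              w4: float = 1.5) -> Tensor:
    """Pull high-anchored ATAC cells onto their RNA partner and its
    cluster centroid (element-wise L1, denominators n*d as defined)."""
    return _anchor_pull(as_tensor(E_a), atac_idx, partner_rows, centroid_rows, n, w4)


def loss_low(E_a, atac_idx, partner_rows, centroid_rows, n: int,
             w4: float = 1.5, w5: float = 0.8) -> Tensor:
    """Same structure as the high-weight pull, damped by w5."""
    return w5 * _anchor_pull(as_tensor(E_a), atac_idx, partner_rows, centroid_rows, n, w4)


def loss_batch(E_a, E_r, w6: float = 0.01) -> Tensor:
    """Match first and second moments of the two modality embeddings:
    w6 * sum_j |sum_i Ea - sum_i Er| / (n*d) + sum_j |sigma_a - sigma_r| / d."""
    E_a, E_r = as_tensor(E_a), as_tensor(E_r)
    n, d = E_a.shape
    mean_term = (E_a.sum(axis=0) - E_r.sum(axis=0)).abs().sum() / (n * d)
    std_term = (E_a.std(axis=0) - E_r.std(axis=0)).abs().sum() / d
    return w6 * mean_term + std_term


def loss_cf(P_r, label_codes) -> Tensor:
    """Classification loss on RNA probability scores.

    Inverse of the mean probability assigned to the true class, plus, for
    misclassified cells, the summed probabilities of classes scoring
    above the true class.
    """
    P_r = as_tensor(P_r)
    label_codes = np.asarray(label_codes, dtype=np.intp)
    correct = gather_rows(P_r, label_codes)
    loss = (correct.mean() + EPS) ** -1
    pred = predict_label(P_r.data)
    wrong = pred != label_codes
    if wrong.any():
        above = P_r.data > P_r.data[np.arange(len(label_codes)), label_codes][:, None]
        mask = (wrong[:, None] & above).astype(np.float64)
        loss = loss + (P_r * mask).sum()
    return loss


def total_loss(terms: dict) -> Tensor:
    """Sum the term dict; raise naming any non-finite contribution."""
    total = None
    for name, t in terms.items():
        t = as_tensor(t)
        if not np.all(np.isfinite(t.data)):
            raise FloatingPointError(f"loss term {name!r} is non-finite")
        total = t if total is None else total + t
    if total is None:
        raise ValueError("no loss terms supplied")
    return total
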