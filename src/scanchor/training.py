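"""Minibatch sampling, the epoch loop and the SGD driver.

Each epoch embeds both full datasets with the current parameters,
refreshes the anchor set (after a supervised warm-up, so mutual nearest
neighbours are searched in a non-random embedding), and then minimises
the summed objective over paired half-batches.  Reference values that
anchor losses need from outside the batch — RNA partner embeddings,
cluster centroids, peak-graph neighbour embeddings — are taken from the
epoch-start full embeddings and treated as constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .anchors import AnchorSet, build_anchor_set
from .data_model import InputError, LabelCodebook, ModalityDataset
from .losses import (
    LossWeights, Minibatch, loss_batch, loss_cf, loss_gas, loss_high,
    loss_low, loss_rna, total_loss,
)
from .network import NetworkParams, classify, embed, init_network
from .preprocess import build_peak_graph

__all__ = ["TrainConfig", "NumericalError", "sample_minibatch", "epoch_batches", "fit"]


class NumericalError(RuntimeError):
    """Training diverged; carries the last finite checkpoint if any."""

    def __init__(self, msg, checkpoint=None):
        super().__init__(msg)
        self.checkpoint = checkpoint


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``batch_size`` counts cells per modality (each minibatch holds
    batch_size RNA plus batch_size ATAC cells).  The anchor machinery
    starts after ``warmup_epochs`` of purely supervised training and is
    refreshed every ``anchor_refresh_period`` epochs.
    """

    batch_size: int = 256
    epochs: int = 100
    learning_rate: float = 0.001
    momentum: float = 0.9
    optimizer: str = "sgd"
    seed: int = 0
    anchor_refresh_period: int = 1
    warmup_epochs: int = 5
    k_mnn: int = 10
    k_graph: int = 15
    k_nn: int = 30
    d: int = 64
    m: int = 50
    rare_threshold: float = 0.03
    w4: float = 1.5
    w5: float = 0.8
    w6: float = 0.01
    s1: float = 0.2
    s2: float = 0.8
    use_anchors: bool = True

    def __post_init__(self):
        for name in ("batch_size", "anchor_refresh_period", "k_mnn",
                     "k_graph", "k_nn", "d", "m"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.epochs < 0:
            raise InputError("epochs must be non-negative")
        if self.optimizer != "sgd":
            raise InputError(f"unknown optimizer {self.optimizer!r}")

    def to_dict(self) -> dict:
        return asdict(self)


class _Stream:
    """Without-replacement index stream that reshuffles when exhausted."""

    def __init__(self, n: int, rng: np.random.Generator):
        self.n = n
        self.rng = rng
        self.pool: list = []

    def draw(self, k: int) -> np.ndarray:
        out: list = []
        while k > 0:
            if not self.pool:
                self.pool = list(self.rng.permutation(self.n))
            take = min(k, len(self.pool))
            out.extend(self.pool[:take])
            del self.pool[:take]
            k -= take
        return np.asarray(out, dtype=np.intp)


def sample_minibatch(rna_ds: ModalityDataset, atac_ds: ModalityDataset,
                     n: int, rng: np.random.Generator) -> Minibatch:
    """One random paired half-batch (n cells per modality)."""
    if n > min(rna_ds.n_cells, atac_ds.n_cells):
        raise InputError(
            f"batch size {n} exceeds a dataset size "
            f"({rna_ds.n_cells} RNA / {atac_ds.n_cells} ATAC cells)"
        )
    rna_idx = rng.choice(rna_ds.n_cells, size=n, replace=False)
    atac_idx = rng.choice(atac_ds.n_cells, size=n, replace=False)
    return Minibatch(rna_idx, atac_idx)


def epoch_batches(n1: int, n2: int, n: int, rng: np.random.Generator):
    """Paired index batches covering one epoch.

    The larger modality is partitioned (each cell seen exactly once per
    epoch, last batch possibly short); the smaller modality cycles
    through reshuffled permutations.
    """
    if n > min(n1, n2):
        raise InputError(f"batch size {n} exceeds min dataset size {min(n1, n2)}")
    driver, other = (n1, n2) if n1 >= n2 else (n2, n1)
    drv = _Stream(driver, rng)
    oth = _Stream(other, rng)
    perm = list(rng.permutation(driver))
    batches = []
    for a in range(0, driver, n):
        d_idx = np.asarray(perm[a:a + n], dtype=np.intp)
        o_idx = oth.draw(len(d_idx))
        if n1 >= n2:
            batches.append(Minibatch(d_idx, o_idx))
        else:
            batches.append(Minibatch(o_idx, d_idx))
    return batches


class _SGD:
    def __init__(self, params, lr: float, momentum: float):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _embed_nograd(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    return X @ params.W1.data + params.b1.data


def rare_fraction(label_codes: np.ndarray, K: int, threshold: float = 0.03) -> float:
    """Proportion of RNA cells in classes below the rare-type threshold."""
    counts = np.bincount(label_codes, minlength=K)
    frac = counts / counts.sum()
    return float(frac[frac < threshold].sum())


def _fold_standardisation(state: dict, mu: np.ndarray, sd: np.ndarray) -> dict:
    """Rewrite f1 so it acts on unstandardised input.

    Training standardises genes internally; because f1 is affine the
    transform folds exactly into the returned weights:
    W1' = W1 / sd, b1' = b1 - (mu/sd) @ W1.
    """
    state = dict(state)
    W1, b1 = state["W1"], state["b1"]
    state["b1"] = b1 - (mu / sd) @ W1
    state["W1"] = W1 / sd[:, None]
    return state


def fit(rna_ds: ModalityDataset, gas_ds: ModalityDataset,
        xp_ds: ModalityDataset, config: TrainConfig,
        weights: LossWeights | None = None):
    """Train the joint embedding; returns (params, anchors, summary, log).

    Inputs are expected normalised (see preprocess) with genes aligned
    across the two modalities and labels present on the RNA side.
    Gene columns are standardised internally (pooled over both
    modalities) to keep the softmax head out of saturation; the inverse
    transform is folded back into the returned affine weights, so the
    checkpoint acts directly on normalised input.
    """
    if rna_ds.feature_ids != gas_ds.feature_ids:
        raise InputError("RNA and GAS gene sets are not aligned")
    if rna_ds.labels is None:
        raise InputError("RNA dataset must carry labels")
    if gas_ds.n_cells != xp_ds.n_cells:
        raise InputError("GAS and peak-space matrices disagree on cell count")

    codebook = LabelCodebook(tuple(sorted(set(rna_ds.labels))))
    y = codebook.encode(rna_ds.labels)
    K = codebook.K
    g = rna_ds.n_features
    rare = rare_fraction(y, K, config.rare_threshold)
    if weights is None:
        weights = LossWeights.from_schedule(
            K, rare, w4=config.w4, w5=config.w5, w6=config.w6,
            s1=config.s1, s2=config.s2,
        )
    w = weights

    if config.d >= g:
        raise InputError(
            f"embedding dimension d={config.d} must be below the shared "
            f"gene count g={g}"
        )
    params = init_network(g, config.d, K, config.seed)
    peak_graph = build_peak_graph(xp_ds, min(config.k_graph, xp_ds.n_cells - 1))
    opt = _SGD(params.parameters(), config.learning_rate, config.momentum)
    rng = np.random.default_rng(config.seed + 1)

    pooled = np.vstack([rna_ds.matrix, gas_ds.matrix])
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0) + 1e-8
    Xr = (rna_ds.matrix - mu) / sd
    Xa = (gas_ds.matrix - mu) / sd
    n1, n2 = Xr.shape[0], Xa.shape[0]
    neighbor_idx = np.stack([peak_graph.neighbors_of(i) for i in range(n2)])

    anchors: AnchorSet | None = None
    summary = None
    log_rows: list = []
    last_good = params.state_dict()

    for epoch in range(config.epochs):
        E_r_full = _embed_nograd(params, Xr)
        E_a_full = _embed_nograd(params, Xa)
        refresh_due = (
            config.use_anchors
            and epoch >= config.warmup_epochs
            and (epoch - config.warmup_epochs) % config.anchor_refresh_period == 0
        )
        if refresh_due:
            anchors, summary = build_anchor_set(
                E_a_full, E_r_full, peak_graph, y,
                k_mnn=min(config.k_mnn, min(n1, n2) - 1), K=K, epoch=epoch,
            )
        high_map = anchors.high_map if anchors else {}
        low_map = anchors.low_map if anchors else {}
        assignment = anchors.atac_cluster_assignment if anchors else {}

        term_sums: dict = {}
        n_batches = 0
        for batch in epoch_batches(n1, n2, min(config.batch_size, min(n1, n2)), rng):
            n = batch.n
            E_r = embed(params, Xr[batch.rna_idx])
            E_a = embed(params, Xa[batch.atac_idx])
            P_r = classify(params, E_r)
            yb = y[batch.rna_idx]
            terms = {"rna": loss_rna(E_r, yb, w.w1, w.w2, w.w3)}
            if anchors is None:
                nv = E_a_full[neighbor_idx[batch.atac_idx]]
                terms["gas"] = loss_gas(E_a, w.w1, w.w2, w.w3, mode="graph",
                                        neighbor_values=nv)
            else:
                groups = [[] for _ in range(K)]
                hi_pos, hi_part, hi_cent = [], [], []
                lo_pos, lo_part, lo_cent = [], [], []
                for pos, gi in enumerate(batch.atac_idx):
                    gi = int(gi)
                    if gi in assignment:
                        groups[assignment[gi]].append(pos)
                    if gi in high_map:
                        hi_pos.append(pos)
                        hi_part.append(E_r_full[high_map[gi]])
                        hi_cent.append(summary.centroids[assignment[gi]])
                    elif gi in low_map:
                        lo_pos.append(pos)
                        lo_part.append(E_r_full[low_map[gi]])
                        lo_cent.append(summary.centroids[assignment[gi]])
                terms["gas"] = loss_gas(E_a, w.w1, w.w2, w.w3, mode="anchored",
                                        anchored_groups=groups)
                terms["high"] = loss_high(
                    E_a, hi_pos, np.array(hi_part).reshape(-1, config.d),
                    np.array(hi_cent).reshape(-1, config.d), n, w.w4)
                terms["low"] = loss_low(
                    E_a, lo_pos, np.array(lo_part).reshape(-1, config.d),
                    np.array(lo_cent).reshape(-1, config.d), n, w.w4, w.w5)
            terms["batch"] = loss_batch(E_a, E_r, w.w6)
            terms["cf"] = loss_cf(P_r, yb)
            try:
                L = total_loss(terms)
            except FloatingPointError as e:
                raise NumericalError(
                    f"training diverged at epoch {epoch}: {e}",
                    checkpoint=_fold_standardisation(last_good, mu, sd),
                ) from e
            opt.zero_grad()
            L.backward()
            opt.step()
            for name, t in terms.items():
                term_sums[name] = term_sums.get(name, 0.0) + t.item()
            term_sums["total"] = term_sums.get("total", 0.0) + L.item()
            n_batches += 1

        for name, s in sorted(term_sums.items()):
            log_rows.append({"epoch": epoch, "term": name, "value": s / n_batches})
        last_good = params.state_dict()

    if anchors is None:
        anchors = AnchorSet([], [], {}, epoch_stamp=-1)
    log = pd.DataFrame(log_rows, columns=["epoch", "term", "value"])
    params = NetworkParams.from_state(
        _fold_standardisation(params.state_dict(), mu, sd)
    )
    return params, anchors, summary, log
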