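"""The shared embedding/classification network.

Both modalities pass through the same map: an affine embedding layer
f1 : R^g -> R^d followed by a prediction head f2 : R^d -> R^K with a
softmax.  The embedding is deliberately affine — the training objective
regularises feature standard deviations and covariances of the embedded
batch, which presumes a linear geometry — and the whole model is small
enough to train on a single CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = ["NetworkParams", "init_network", "embed", "classify", "softmax", "predict_label"]


@dataclass
class NetworkParams:
    """Learnable parameters of f1 (embed) and f2 (classify)."""

    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor
    g: int
    d: int
    K: int
    seed: int
    hidden: tuple = field(default_factory=tuple)  # reserved for deeper variants

    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def state_dict(self) -> dict:
        return {
            "W1": self.W1.data, "b1": self.b1.data,
            "W2": self.W2.data, "b2": self.b2.data,
            "g": self.g, "d": self.d, "K": self.K, "seed": self.seed,
        }

    @classmethod
    def from_state(cls, state: dict) -> "NetworkParams":
        return cls(
            W1=Tensor(state["W1"], requires_grad=True),
            b1=Tensor(state["b1"], requires_grad=True),
            W2=Tensor(state["W2"], requires_grad=True),
            b2=Tensor(state["b2"], requires_grad=True),
            g=int(state["g"]), d=int(state["d"]), K=int(state["K"]),
            seed=int(state["seed"]),
        )

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path) -> "NetworkParams":
        with np.load(path) as data:
            return cls.from_state({k: data[k] for k in data.files})


def init_network(g: int, d: int = 64, K: int = 2, seed: int = 0) -> NetworkParams:
    """Seeded fan-in uniform initialisation; biases start at zero.

    Weight bounds follow the Kaiming-uniform rule sqrt(6 / fan_in).
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    if not 1 <= d < g:
        raise ValueError(f"need 1 <= d < g, got d={d}, g={g}")
    rng = np.random.default_rng(seed)
    lim1 = np.sqrt(6.0 / g)
    lim2 = np.sqrt(6.0 / d)
    return NetworkParams(
        W1=Tensor(rng.uniform(-lim1, lim1, size=(g, d)), requires_grad=True),
        b1=Tensor(np.zeros(d), requires_grad=True),
        W2=Tensor(rng.uniform(-lim2, lim2, size=(d, K)), requires_grad=True),
        b2=Tensor(np.zeros(K), requires_grad=True),
        g=g, d=d, K=K, seed=seed,
    )


def embed(params: NetworkParams, X) -> Tensor:
    """f1: affine map of cells x g input rows to cells x d embeddings."""
    X = as_tensor(X)
    if X.shape[1] != params.g:
        raise ValueError(f"input has {X.shape[1]} features, network expects {params.g}")
    if not np.all(np.isfinite(X.data)):
        raise ValueError("non-finite values in network input")
    return X @ params.W1 + params.b1


def softmax(logits: Tensor) -> Tensor:
    """Row-wise softmax; the max shift is treated as a constant."""
    logits = as_tensor(logits)
    shift = logits - logits.data.max(axis=1, keepdims=True)
    e = shift.exp()
    return e / e.sum(axis=1, keepdims=True)


def classify(params: NetworkParams, E) -> Tensor:
    """f2: per-cell K-class probability scores from embeddings."""
    E = as_tensor(E)
    if E.shape[1] != params.d:
        raise ValueError(f"embedding has {E.shape[1]} dims, network expects {params.d}")
    return softmax(E @ params.W2 + params.b2)


def predict_label(prob_rows: np.ndarray) -> np.ndarray:
    """Argmax class per row; ties resolved to the lowest class index."""
    prob_rows = np.atleast_2d(np.asarray(prob_rows, dtype=np.float64))
    return prob_rows.argmax(axis=1)  # np.argmax returns the first maximum
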