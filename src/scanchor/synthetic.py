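"""Seeded generator of matched dual-modality datasets.

Emulates the inputs the label-transfer pipeline consumes: an annotated
scRNA-seq count matrix, an unannotated GAS matrix over the same genes,
and a low-dimensional peak-space representation, all sharing a latent
cluster structure with one designated rare cluster.

Cells live in a latent space where each cluster has a Gaussian blob
around its centre.  RNA counts are Poisson draws with a softplus link
through a fixed random gene loading.  The ATAC side uses the SAME gene
loading but its latent positions are offset by a cluster-specific shift
vector — a stand-in for the biological lag between chromatin opening
and transcription, which behaves like a batch effect that global
centring cannot remove — plus extra dropout.  The peak-space matrix is
a different random linear read-out of the ATAC latent positions, so
peak-space neighbourhoods agree with the true clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .data_model import InputError, ModalityDataset

__all__ = ["SimConfig", "generate"]

_LATENT_DIM = 10


@dataclass
class SimConfig:
    """Generator knobs.

    ``sep`` scales cluster-centre spread relative to the within-cluster
    noise (``noise_sd``); ``shift`` is the magnitude of each cluster's
    modality offset in units of ``sep`` (the scale separating cell
    states), so the injected batch effect stays commensurate with the
    biological structure rather than being swallowed by count noise;
    ``rare_fraction`` is the expected proportion of cells in the
    designated rare cluster (the last class).
    """

    n1: int = 2000
    n2: int = 2000
    K: int = 5
    g: int = 300
    m: int = 20
    rare_fraction: float = 0.03
    sep: float = 3.0
    shift: float = 0.5
    noise_sd: float = 1.0
    dropout_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("n1", "n2", "K", "g", "m"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.K < 2:
            raise InputError("need at least 2 clusters")
        if not 0.0 < self.rare_fraction <= 1.0 / self.K:
            raise InputError(
                f"rare_fraction must lie in (0, 1/K]; got {self.rare_fraction} "
                f"with K={self.K}"
            )
        if self.m >= min(self.n2, self.g):
            raise InputError("m must be below min(n2, g)")

    def to_dict(self) -> dict:
        return asdict(self)


def _class_probs(cfg: SimConfig) -> np.ndarray:
    p = np.full(cfg.K, (1.0 - cfg.rare_fraction) / (cfg.K - 1))
    p[-1] = cfg.rare_fraction
    return p


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def generate(cfg: SimConfig):
    """Draw one dataset triple; byte-identical for a fixed seed.

    Returns ``(rna, gas, xp, truth)``: the RNA dataset carries labels,
    the GAS/peak datasets do not, and ``truth`` is a (cell_id, label)
    DataFrame holding the hidden ATAC labels.
    """
    rng = np.random.default_rng(cfg.seed)
    L = _LATENT_DIM
    centers = rng.normal(scale=cfg.sep, size=(cfg.K, L))
    shift_dirs = rng.normal(size=(cfg.K, L))
    shift_dirs /= np.linalg.norm(shift_dirs, axis=1, keepdims=True)
    gene_loading = rng.normal(scale=1.0 / np.sqrt(L), size=(L, cfg.g))
    peak_loading = rng.normal(scale=1.0 / np.sqrt(L), size=(L, cfg.m))

    probs = _class_probs(cfg)
    y_rna = rng.choice(cfg.K, size=cfg.n1, p=probs)
    y_atac = rng.choice(cfg.K, size=cfg.n2, p=probs)
    if len(set(y_rna.tolist())) < cfg.K:
        raise InputError(
            "rare_fraction too small: an RNA class drew no cells; "
            "increase n1 or rare_fraction"
        )

    latent_rna = centers[y_rna] + rng.normal(scale=cfg.noise_sd, size=(cfg.n1, L))
    latent_atac = centers[y_atac] + rng.normal(scale=cfg.noise_sd, size=(cfg.n2, L))
    latent_atac_shifted = latent_atac + cfg.shift * cfg.sep * shift_dirs[y_atac]

    rna_counts = rng.poisson(_softplus(latent_rna @ gene_loading)).astype(float)
    gas_counts = rng.poisson(_softplus(latent_atac_shifted @ gene_loading)).astype(float)
    if cfg.dropout_rate > 0:
        keep = rng.random(size=gas_counts.shape) >= cfg.dropout_rate
        gas_counts *= keep

    xp_coords = latent_atac @ peak_loading + rng.normal(scale=0.1, size=(cfg.n2, cfg.m))

    class_names = np.array([f"type_{k:02d}" for k in range(cfg.K)], dtype=object)
    genes = [f"gene_{j:04d}" for j in range(cfg.g)]
    rna_ids = [f"r{i:05d}" for i in range(cfg.n1)]
    atac_ids = [f"a{i:05d}" for i in range(cfg.n2)]

    rna = ModalityDataset(rna_counts, rna_ids, genes, "rna",
                          labels=class_names[y_rna])
    gas = ModalityDataset(gas_counts, atac_ids, genes, "gas")
    xp = ModalityDataset(xp_coords, atac_ids,
                         [f"dim_{j}" for j in range(cfg.m)], "peak_pca")
    truth = pd.DataFrame({"cell_id": atac_ids, "label": class_names[y_atac]})
    return rna, gas, xp, truth
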