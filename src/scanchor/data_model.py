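"""Domain containers and file I/O for cross-modality label transfer.

Three matrices drive the method: an annotated scRNA-seq expression matrix
(cells x genes), a gene-activity-score (GAS) matrix summarising scATAC-seq
accessibility over the same genes, and a low-dimensional representation of
the scATAC peak space.  On disk the sparse matrices follow the CellRanger
convention (Matrix Market, features x cells, with one-column feature and
barcode TSVs); in memory everything is oriented cells x features.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "InputError",
    "ModalityDataset",
    "LabelCodebook",
    "MetricReport",
    "read_mtx",
    "write_mtx",
    "read_labels",
    "read_dense",
    "align_genes",
]

VALID_TAGS = ("rna", "gas", "peak", "peak_pca")


class InputError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class ModalityDataset:
    """One modality's matrix plus cell/feature identifiers.

    ``matrix`` is dense float64, cells x features.  For count-like
    modalities (``rna``, ``gas``, ``peak``) entries must be finite and
    non-negative; PCA coordinates (``peak_pca``) may be any finite value.
    """

    matrix: np.ndarray
    cell_ids: list
    feature_ids: list
    modality_tag: str
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.cell_ids = list(self.cell_ids)
        self.feature_ids = list(self.feature_ids)
        if self.modality_tag not in VALID_TAGS:
            raise InputError(
                f"modality_tag must be one of {VALID_TAGS}, got {self.modality_tag!r}"
            )
        n, f = self.matrix.shape
        if n != len(self.cell_ids):
            raise InputError(
                f"matrix has {n} rows but {len(self.cell_ids)} cell ids"
            )
        if f != len(self.feature_ids):
            raise InputError(
                f"matrix has {f} columns but {len(self.feature_ids)} feature ids"
            )
        if len(set(self.cell_ids)) != n:
            raise InputError("cell ids are not unique")
        if len(set(self.feature_ids)) != f:
            raise InputError("feature ids are not unique")
        if not np.all(np.isfinite(self.matrix)):
            raise InputError("matrix contains non-finite entries")
        if self.modality_tag in ("rna", "gas", "peak") and np.any(self.matrix < 0):
            raise InputError(f"{self.modality_tag} matrix has negative entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise InputError("labels length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class LabelCodebook:
    """Ordered cell-type classes and their integer codes.

    Classes are kept in lexicographic order so integer codes, centroid
    rows and argmax tie-breaks are reproducible across runs.
    """

    classes: tuple

    def __post_init__(self):
        if len(set(self.classes)) != len(self.classes):
            raise InputError("class names are not unique")
        if len(self.classes) < 2:
            raise InputError(f"need at least 2 classes, got {len(self.classes)}")
        if list(self.classes) != sorted(self.classes):
            raise InputError("codebook classes must be lexicographically sorted")

    @property
    def K(self) -> int:
        return len(self.classes)

    def encode(self, labels: Sequence) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.classes)}
        try:
            return np.array([index[l] for l in labels], dtype=np.intp)
        except KeyError as e:
            raise InputError(f"label {e.args[0]!r} not in codebook") from None

    def decode(self, codes: Sequence[int]) -> np.ndarray:
        arr = np.asarray(self.classes, dtype=object)
        return arr[np.asarray(codes, dtype=np.intp)]


@dataclass
class MetricReport:
    """Named scalar metrics plus optional per-class and rare-class tables."""

    scalars: dict = field(default_factory=dict)
    per_class: Optional[pd.DataFrame] = None
    rare: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.scalars.items():
            if not np.isfinite(v):
                raise ValueError(f"metric {k!r} is not finite: {v}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"metric": list(self.scalars), "value": list(self.scalars.values())}
        )


# ----------------------------------------------------------------------
# readers / writers


def _read_lines(path: str) -> list:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_mtx(path_matrix, path_features, path_barcodes, modality_tag="rna") -> ModalityDataset:
    """Read a CellRanger-style MTX triplet into a cells x features dataset.

    The MTX file is features x cells and is transposed on load; counts are
    preserved exactly.
    """
    mat = scipy.io.mmread(path_matrix)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=np.float64)
    features = _read_lines(path_features)
    barcodes = _read_lines(path_barcodes)
    n_feat, n_cells = mat.shape
    if len(features) != n_feat:
        raise InputError(
            f"{path_features}: {len(features)} features but matrix "
            f"{path_matrix} declares {n_feat} rows"
        )
    if len(barcodes) != n_cells:
        raise InputError(
            f"{path_barcodes}: {len(barcodes)} barcodes but matrix "
            f"{path_matrix} declares {n_cells} columns"
        )
    return ModalityDataset(mat.T, barcodes, features, modality_tag)


def write_mtx(ds: ModalityDataset, outdir, prefix="") -> None:
    """Write a dataset as matrix.mtx + features.tsv + barcodes.tsv."""
    os.makedirs(outdir, exist_ok=True)
    sp = scipy.sparse.coo_matrix(ds.matrix.T)  # features x cells on disk
    scipy.io.mmwrite(os.path.join(outdir, f"{prefix}matrix.mtx"), sp)
    with open(os.path.join(outdir, f"{prefix}features.tsv"), "w") as fh:
        fh.write("".join(f"{f}\n" for f in ds.feature_ids))
    with open(os.path.join(outdir, f"{prefix}barcodes.tsv"), "w") as fh:
        fh.write("".join(f"{b}\n" for b in ds.cell_ids))


def read_labels(path, cell_ids):
    """Read a two-column (cell_id, label) TSV, ordered to ``cell_ids``.

    Returns ``(labels, codebook)`` where labels is an object array aligned
    with ``cell_ids`` and the codebook holds the lexicographically sorted
    class set.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected two columns (cell_id, label)")
    ids = df.iloc[:, 0].tolist()
    dup = sorted({i for i in ids if ids.count(i) > 1}) if len(set(ids)) != len(ids) else []
    if dup:
        raise InputError(f"{path}: duplicate cell ids {dup[:10]}")
    mapping = dict(zip(ids, df.iloc[:, 1].tolist()))
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise InputError(f"{path}: missing labels for cells {missing[:10]}")
    labels = np.array([mapping[c] for c in cell_ids], dtype=object)
    codebook = LabelCodebook(tuple(sorted(set(labels))))
    return labels, codebook


def read_dense(path, modality_tag="peak_pca", cell_ids=None) -> ModalityDataset:
    """Read a whitespace-delimited dense matrix (cells x features)."""
    mat = np.loadtxt(path, dtype=np.float64, ndmin=2)
    n, m = mat.shape
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(n)]
    return ModalityDataset(mat, cell_ids, [f"dim_{j}" for j in range(m)], modality_tag)


def align_genes(rna: ModalityDataset, gas: ModalityDataset):
    """Restrict both modalities to their shared genes, in a single order.

    The shared order is the RNA feature order filtered to the intersection,
    which makes the operation idempotent.
    """
    for ds in (rna, gas):
        if ds.modality_tag not in ("rna", "gas"):
            raise InputError(f"align_genes expects rna/gas, got {ds.modality_tag}")
    gas_set = set(gas.feature_ids)
    shared = [f for f in rna.feature_ids if f in gas_set]
    if not shared:
        raise InputError("no genes shared between the two modalities")
    r_idx = [rna.feature_ids.index(f) for f in shared]
    g_pos = {f: i for i, f in enumerate(gas.feature_ids)}
    g_idx = [g_pos[f] for f in shared]
    rna_out = ModalityDataset(
        rna.matrix[:, r_idx], rna.cell_ids, shared, rna.modality_tag, rna.labels
    )
    gas_out = ModalityDataset(
        gas.matrix[:, g_idx], gas.cell_ids, shared, gas.modality_tag, gas.labels
    )
    return rna_out, gas_out
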