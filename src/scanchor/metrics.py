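"""Evaluation metrics: ARI, AMI, per-class and rare-stratified
classification scores, silhouette and modality silhouette.

ARI, AMI and the silhouette coefficient are delegated to scikit-learn.
AMI uses the max(H(U), H(V)) normaliser.  Classification metrics are
computed from the per-class confusion counts directly because the
rare-type stratification (macro-F1 over classes whose true proportion
falls below each threshold) has no library equivalent.  The modality
silhouette groups cells by modality instead of by type: LOWER values
mean better cross-modality mixing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import (
    adjusted_mutual_info_score, adjusted_rand_score, silhouette_samples,
)

from .data_model import MetricReport

__all__ = [
    "ari", "ami", "classification_metrics", "silhouette",
    "modality_silhouette", "RARE_THRESHOLDS",
]

RARE_THRESHOLDS = (0.10, 0.05, 0.03, 0.01)


def _check_lengths(y_true, y_pred):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    if len(y_true) < 2:
        raise ValueError("need at least 2 cells")
    return y_true, y_pred


def ari(y_true, y_pred) -> float:
    """Adjusted Rand index of the predicted vs reference partition."""
    y_true, y_pred = _check_lengths(y_true, y_pred)
    return float(adjusted_rand_score(y_true, y_pred))


def ami(y_true, y_pred) -> float:
    """Adjusted mutual information, normalised by max(H(U), H(V))."""
    y_true, y_pred = _check_lengths(y_true, y_pred)
    if len(set(y_true)) == 1 and len(set(y_pred)) == 1:
        warnings.warn("degenerate single-class labelings; AMI set to 0")
        return 0.0
    return float(adjusted_mutual_info_score(y_true, y_pred, average_method="max"))


def classification_metrics(y_true, y_pred,
                           rare_thresholds=RARE_THRESHOLDS) -> MetricReport:
    """Per-class TP/FP/FN, recall, precision, F1, macro/micro overall
    scores, and macro-F1 restricted to rare classes per threshold.

    Classes are the union of true and predicted label sets; zero
    denominators yield 0 (flagged in the per-class table).
    """
    y_true, y_pred = _check_lengths(y_true, y_pred)
    classes = sorted(set(y_true) | set(y_pred))
    rows = []
    n = len(y_true)
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        recall = tp / (tp + fn) if tp + fn else 0.0
        precision = tp / (tp + fp) if tp + fp else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        rows.append({
            "class": c, "n_true": tp + fn, "proportion": (tp + fn) / n,
            "TP": tp, "FP": fp, "FN": fn,
            "recall": recall, "precision": precision, "f1": f1,
            "zero_division": (tp + fp == 0) or (tp + fn == 0),
        })
    table = pd.DataFrame(rows)
    scalars = {
        "accuracy": float(np.mean(y_true == y_pred)),
        "macro_recall": float(table["recall"].mean()),
        "macro_precision": float(table["precision"].mean()),
        "macro_f1": float(table["f1"].mean()),
    }
    tp_all = int(table["TP"].sum())
    scalars["micro_recall"] = tp_all / max(tp_all + int(table["FN"].sum()), 1)
    scalars["micro_precision"] = tp_all / max(tp_all + int(table["FP"].sum()), 1)
    mr, mp = scalars["micro_recall"], scalars["micro_precision"]
    scalars["micro_f1"] = 2 * mp * mr / (mp + mr) if mp + mr else 0.0
    rare = {}
    for thr in rare_thresholds:
        mask = (table["proportion"] < thr) & (table["n_true"] > 0)
        rare[thr] = {
            "classes": table.loc[mask, "class"].tolist(),
            "macro_f1": float(table.loc[mask, "f1"].mean()) if mask.any() else None,
        }
    return MetricReport(scalars=scalars, per_class=table, rare=rare)


def silhouette(points, groups, max_cells: int = 5000, seed: int = 0):
    """Mean silhouette and per-point S(i) over Euclidean distances.

    S(i) = (b(i) - a(i)) / max(a(i), b(i)); singleton-group points score
    0.  Above ``max_cells`` points a seeded subsample is used.
    """
    points = np.asarray(points, dtype=np.float64)
    groups = np.asarray(groups)
    if len(points) != len(groups):
        raise ValueError("points and groups must have equal length")
    if len(set(groups.tolist())) < 2:
        raise ValueError("silhouette requires at least two groups")
    if len(points) > max_cells:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(points), size=max_cells, replace=False))
        points, groups = points[keep], groups[keep]
    samples = silhouette_samples(points, groups, metric="euclidean")
    return float(samples.mean()), samples


def modality_silhouette(joint_embedding, modality_tags, max_cells: int = 5000,
                        seed: int = 0) -> float:
    """Silhouette with cells grouped by modality; lower = better mixed."""
    mean, _ = silhouette(joint_embedding, modality_tags,
                         max_cells=max_cells, seed=seed)
    return mean
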