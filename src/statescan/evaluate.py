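"""Recovery scoring of analyses against synthetic ground truth."""

from __future__ import annotations

from itertools import permutations

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = ["label_agreement", "pc1_two_means_silhouette", "occupancy_error"]


def label_agreement(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Best fraction of matching labels over all mappings of predicted ids to truth ids.

    Label ids are arbitrary, so agreement is scored after the optimal
    relabeling (exhaustive over the predicted id set; intended for small
    cluster counts).
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(predicted) != len(truth):
        raise ValueError("label arrays must have equal length")
    pred_ids = list(dict.fromkeys(predicted.tolist()))
    true_ids = list(dict.fromkeys(truth.tolist()))
    if len(pred_ids) > 6:
        raise ValueError("too many predicted labels for exhaustive matching")
    targets = true_ids + [None] * max(0, len(pred_ids) - len(true_ids))
    best = 0.0
    for perm in permutations(targets, len(pred_ids)):
        mapping = dict(zip(pred_ids, perm))
        mapped = np.array([mapping[p] for p in predicted], dtype=object)
        best = max(best, float(np.mean(mapped == truth)))
    return best


def pc1_two_means_silhouette(pc1: np.ndarray, random_state: int = 0) -> float:
    """Silhouette of a 2-means split of the PC1 projections (state separability)."""
    pc1 = np.asarray(pc1, float).reshape(-1, 1)
    labels = KMeans(n_clusters=2, n_init=10, random_state=random_state).fit_predict(pc1)
    if len(set(labels)) < 2:
        return 0.0
    return float(silhouette_score(pc1, labels))


def occupancy_error(recovered: dict[str, float], truth: dict[str, float],
                    mapping: dict[str, str] | None = None) -> float:
    """Mean absolute occupancy error over the states shared by both tables."""
    mapping = mapping or {}
    errors = []
    for name, p in truth.items():
        key = mapping.get(name, name)
        if key in recovered:
            errors.append(abs(recovered[key] - p))
    if not errors:
        raise ValueError("no comparable states between recovered and truth")
    return float(np.mean(errors))
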