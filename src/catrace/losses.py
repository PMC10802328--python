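"""Class weighting and weighted cross-entropy for voxel classification.

Voxel labels are extremely imbalanced (almost all voxels contain no
backbone atom), so each class is down-weighted by its frequency:
``w_c = 1 - n_c / sum_k n_k``. The weights of C classes always sum to
C - 1. The loss is the weight-scaled negative log-softmax averaged over
the sample count N (not over the sum of applied weights, which is what
some library implementations normalize by).
"""

from __future__ import annotations

import numpy as np


def class_weights(class_counts) -> np.ndarray:
    """Per-class weights ``1 - n_c / total`` in class-index order."""
    counts = np.asarray(class_counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("class_counts must be a 1-D vector of >= 2 classes")
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("class counts sum to zero")
    return 1.0 - counts / total


def weighted_cross_entropy(logits, labels, weights) -> float:
    """Mean weighted cross-entropy over a batch.

    ``loss = -(1/N) * sum_n w_{y_n} * log softmax(x_n)_{y_n}``
    """
    x = np.asarray(logits, dtype=float)
    y = np.asarray(labels)
    w = np.asarray(weights, dtype=float)
    if x.ndim != 2:
        raise ValueError("logits must be (N, C)")
    n, c = x.shape
    if y.shape != (n,):
        raise ValueError("labels must be (N,)")
    if w.shape != (c,):
        raise ValueError(f"weights must have {c} entries")
    if not np.all(np.isfinite(x)):
        raise ValueError("logits must be finite")
    if np.any(y < 0) or np.any(y >= c):
        raise ValueError("label out of range")
    # log-softmax, numerically stable
    z = x - x.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    picked = logp[np.arange(n), y]
    return float(-(w[y] * picked).sum() / n)
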