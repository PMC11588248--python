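"""Pair-based clustering agreement metrics.

All four metrics are defined over the C(m, 2) unordered pairs of
observations: a pair is a true positive when both partitions place it in
one cluster, a true negative when both keep it apart. The orientation is
fixed: the *first* partition is the truth. Counts come from
scikit-learn's contingency-based pair confusion (O(m + K^2)); the
adjusted Rand index is computed from those counts via the Hubert-Arabie
identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.cluster import pair_confusion_matrix

__all__ = [
    "PairConfusion",
    "pair_confusion",
    "rand_index",
    "adjusted_rand_index",
    "tpr_tnr",
]


@dataclass(frozen=True)
class PairConfusion:
    """Pair-level confusion counts; truth is the first partition."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def n_pairs(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def _labels(partition) -> np.ndarray:
    """Accept a Partition-like object (``.labels``) or a plain sequence."""
    labels = getattr(partition, "labels", partition)
    return np.asarray(labels)


def _check_aligned(truth, pred) -> tuple[np.ndarray, np.ndarray]:
    lt, lp = _labels(truth), _labels(pred)
    if lt.shape != lp.shape or lt.ndim != 1:
        raise ValueError("partitions must be 1-d and of equal length")
    ids_t, ids_p = getattr(truth, "ids", None), getattr(pred, "ids", None)
    if ids_t is not None and ids_p is not None and list(ids_t) != list(ids_p):
        raise ValueError("partitions are over different observation ids")
    return lt, lp


def pair_confusion(truth, pred) -> PairConfusion:
    """Pair confusion counts (TP, FP, FN, TN) over unordered pairs.

    TP: together in both; TN: apart in both; FN: together in truth only;
    FP: together in prediction only.
    """
    lt, lp = _check_aligned(truth, pred)
    if lt.size < 2:
        raise ValueError("pair metrics need at least 2 observations")
    C = pair_confusion_matrix(lt, lp)  # ordered pairs; halve for unordered
    return PairConfusion(TP=int(C[1, 1] // 2), FP=int(C[0, 1] // 2),
                         FN=int(C[1, 0] // 2), TN=int(C[0, 0] // 2))


def rand_index(truth, pred) -> float:
    """Rand index: proportion of pairs on which the partitions agree."""
    pc = pair_confusion(truth, pred)
    return (pc.TP + pc.TN) / pc.n_pairs


def adjusted_rand_index(truth, pred) -> float:
    """Hubert-Arabie adjusted Rand index.

    1 iff the partitions are identical up to relabeling; expectation about
    0 for independent random labelings. When the chance-correction
    denominator degenerates (both partitions all-singletons or both a
    single cluster), returns 1 if the partitions are identical up to
    relabeling and 0 otherwise.
    """
    pc = pair_confusion(truth, pred)
    a, b, c, d = pc.TP, pc.FN, pc.FP, pc.TN
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    if denom == 0:
        # both trivial: agreement is all-or-nothing
        return 1.0 if b == 0 and c == 0 else 0.0
    return 2.0 * (a * d - b * c) / denom


def tpr_tnr(truth, pred) -> tuple[float | None, float | None]:
    """True positive and true negative clustering rates over pairs.

    TPR = TP / (TP + FN), TNR = TN / (TN + FP); a rate whose denominator
    is zero (no positive, resp. negative, pairs in the truth) is returned
    as ``None`` rather than 0.
    """
    pc = pair_confusion(truth, pred)
    tpr = pc.TP / (pc.TP + pc.FN) if pc.TP + pc.FN > 0 else None
    tnr = pc.TN / (pc.TN + pc.FP) if pc.TN + pc.FP > 0 else None
    return tpr, tnr
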