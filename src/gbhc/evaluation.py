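"""Clustering-quality indices: adjusted Rand index and biological homogeneity.

The adjusted Rand index (Hubert & Arabie) is the pair-counting Rand index
corrected for chance agreement: with contingency counts ``n_ij`` between two
partitions,

    ARI = (sum_ij C(n_ij,2) - E) / (max_index - E),

where ``E`` is the expected sum under random label permutation.  Identical
partitions score 1; independent ones score about 0, and mild negative values
are possible (and preserved — no clamping).

The biological homogeneity index (BHI) scores a partition against an
item -> functional-class annotation map: for each cluster, the fraction of
annotated member pairs sharing at least one class, averaged over clusters
with at least two annotated members.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np

from .partition import Partition

__all__ = ["Partition", "adjusted_rand_index", "bhi", "cluster_count"]


def _label_array(P) -> np.ndarray:
    if isinstance(P, Partition):
        return P.labels
    return np.asarray(P)


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def adjusted_rand_index(P, Q) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    Accepts :class:`Partition` objects or bare label sequences over the same
    observations (matching ids when both are partitions).
    """
    if isinstance(P, Partition) and isinstance(Q, Partition):
        if len(P) != len(Q) or set(P.ids.tolist()) != set(Q.ids.tolist()):
            raise ValueError("partitions cover different observation sets")
        order = {v: i for i, v in enumerate(P.ids.tolist())}
        q_labels = np.empty(len(Q), dtype=object)
        for i, v in zip(Q.ids.tolist(), Q.labels):
            q_labels[order[i]] = v
        p_labels = P.labels
    else:
        p_labels = _label_array(P)
        q_labels = _label_array(Q)
        if len(p_labels) != len(q_labels):
            raise ValueError("partitions have different lengths")
    n = len(p_labels)
    if n < 2:
        return 1.0
    _, pi = np.unique(np.asarray(p_labels, dtype=str), return_inverse=True)
    _, qi = np.unique(np.asarray(q_labels, dtype=str), return_inverse=True)
    kp, kq = pi.max() + 1, qi.max() + 1
    table = np.zeros((kp, kq))
    np.add.at(table, (pi, qi), 1)
    sum_ij = _comb2(table).sum()
    sum_a = _comb2(table.sum(axis=1)).sum()
    sum_b = _comb2(table.sum(axis=0)).sum()
    total = _comb2(np.array([n]))[0]
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both trivial partitions: identical by definition
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def bhi(P: Partition, annotations: Mapping) -> float:
    """Biological homogeneity of a partition under a functional annotation map.

    ``annotations`` maps observation id to a set of class identifiers; items
    missing from the map or mapped to an empty set are treated as
    unannotated and excluded.  Clusters with fewer than two annotated
    members do not enter the average.  Raises if no cluster has an eligible
    pair.
    """
    scores = []
    for _, members in P.clusters().items():
        annotated = [
            frozenset(annotations[i])
            for i in members.tolist()
            if i in annotations and len(annotations[i]) > 0
        ]
        m = len(annotated)
        if m < 2:
            continue
        hits = sum(
            1
            for u in range(m)
            for v in range(u + 1, m)
            if annotated[u] & annotated[v]
        )
        scores.append(hits / (m * (m - 1) / 2))
    if not scores:
        raise ValueError(
            "BHI undefined: no cluster has two or more annotated members"
        )
    return float(np.mean(scores))


def cluster_count(P: Partition) -> int:
    """Number of distinct cluster labels in the partition."""
    return P.n_clusters()
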