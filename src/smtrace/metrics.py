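"""Embedding-space metrics: exact k-NN, label Self-Consistency Score and
Local Shannon Entropy.

Both metrics operate on trace-level embeddings with exact Euclidean nearest
neighbors; ties are broken deterministically by lower trace index and the
query point is never its own neighbor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NeighborIndex",
    "knn",
    "self_consistency_score",
    "local_shannon_entropy",
    "lowest_entropy_subset",
]


@dataclass
class NeighborIndex:
    embeddings: np.ndarray   # (N, D)
    k: int
    neighbors: np.ndarray    # (N, k) int, sorted by distance then index
    distances: np.ndarray    # (N, k)


def knn(embeddings: np.ndarray, k: int, chunk: int = 1024) -> NeighborIndex:
    """Exact Euclidean k-NN with self excluded and index tie-breaking."""
    Z = np.asarray(embeddings, dtype=np.float64)
    N = Z.shape[0]
    if not (0 < k < N):
        raise ValueError(f"k must satisfy 0 < k < N ({k=}, {N=})")
    nbrs = np.empty((N, k), dtype=np.int64)
    dists = np.empty((N, k))
    sq = (Z * Z).sum(axis=1)
    for s in range(0, N, chunk):
        e = min(N, s + chunk)
        d2 = sq[s:e, None] + sq[None, :] - 2.0 * (Z[s:e] @ Z.T)
        np.maximum(d2, 0.0, out=d2)
        d2[np.arange(s, e) - s, np.arange(s, e)] = np.inf  # exclude self
        order = np.argsort(d2, axis=1, kind="stable")[:, :k]
        nbrs[s:e] = order
        dists[s:e] = np.sqrt(np.take_along_axis(d2, order, axis=1))
    return NeighborIndex(Z, k, nbrs, dists)


def self_consistency_score(
    index: NeighborIndex,
    labels: np.ndarray,
    label_value=None,
    k: int | None = None,
) -> float | dict:
    """Label Self-Consistency Score.

    SCS(l) = (1 / (k N)) * sum_i sum_{j in NN(i,k)} [y_i = l][y_i = y_j].
    With ``label_value=None`` returns a dict of per-label scores plus the
    aggregate (sum over labels), which equals the mean k-NN label-agreement
    probability over all traces.
    """
    labels = np.asarray(labels)
    N = labels.shape[0]
    if labels.shape[0] != index.embeddings.shape[0]:
        raise ValueError("labels length must match the index")
    k = index.k if k is None else k
    if k > index.k:
        raise ValueError(f"requested k={k} exceeds index k={index.k}")
    nn = index.neighbors[:, :k]
    agree = labels[:, None] == labels[nn]          # (N, k)

    def score_for(l) -> float:
        if not np.any(labels == l):
            if label_value is not None:
                raise ValueError(f"unknown label value {l!r}")
            return 0.0
        sel = labels == l
        return float(agree[sel].sum() / (k * N))

    if label_value is not None:
        if not np.any(labels == label_value):
            raise ValueError(f"unknown label value {label_value!r}")
        return score_for(label_value)
    values = [v for v in np.unique(labels)]
    per_label = {v: score_for(v) for v in values}
    return {"per_label": per_label, "aggregate": float(sum(per_label.values()))}


def local_shannon_entropy(
    index: NeighborIndex,
    conditions: np.ndarray,
    k: int | None = None,
    base: float = np.e,
) -> np.ndarray:
    """Per-trace Shannon entropy of the conditions of {self} U k neighbors.

    P(c) = (1/(1+k)) * ([y_i = c] + sum_{j in NN(i)} [y_j = c]);
    S(x_i) = -sum_c P(c) log P(c), natural log by default.
    """
    conditions = np.asarray(conditions)
    if conditions.shape[0] != index.embeddings.shape[0]:
        raise ValueError("conditions length must match the index")
    k = index.k if k is None else k
    if k > index.k:
        raise ValueError(f"requested k={k} exceeds index k={index.k}")
    cats, codes = np.unique(conditions, return_inverse=True)
    nn = index.neighbors[:, :k]
    N = codes.shape[0]
    counts = np.zeros((N, cats.size))
    np.add.at(counts, (np.arange(N), codes), 1.0)            # self
    for j in range(k):
        np.add.at(counts, (np.arange(N), codes[nn[:, j]]), 1.0)
    p = counts / (1.0 + k)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    S = -terms.sum(axis=1)
    if base != np.e:
        S = S / np.log(base)
    return np.maximum(S, 0.0)


def lowest_entropy_subset(
    entropies: np.ndarray,
    fraction: float,
    conditions: np.ndarray | None = None,
) -> dict:
    """Indices of the floor(fraction*N) lowest-entropy traces (ties by index)."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    entropies = np.asarray(entropies)
    n_keep = int(np.floor(fraction * entropies.shape[0]))
    order = np.argsort(entropies, kind="stable")
    idx = np.sort(order[:n_keep])
    out = {"indices": idx, "n": n_keep}
    if conditions is not None:
        conditions = np.asarray(conditions)
        cats, counts = np.unique(conditions[idx], return_counts=True)
        out["composition"] = dict(zip(cats.tolist(), counts.tolist()))
    return out
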