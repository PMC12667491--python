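"""Deep-embedded-clustering refinement head.

Student-t soft assignment of spots to trainable centroids, a sharpened
target distribution recomputed periodically, and the KL objective pulling
the soft assignment toward the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from ._autograd import Parameter, Tensor, log

__all__ = [
    "ClusterState",
    "init_centroids",
    "soft_assign",
    "target_distribution",
    "loss_dec",
]


@dataclass
class ClusterState:
    centroids: np.ndarray  # (J, d_f)
    Q: np.ndarray | None = None  # (n, J) soft assignment
    P: np.ndarray | None = None  # (n, J) target, held constant between refreshes

    @property
    def J(self) -> int:
        return self.centroids.shape[0]


def init_centroids(Z: np.ndarray, J: int, seed: int) -> np.ndarray:
    """K-means (k-means++ init, 20 restarts) on Z; centroid = cluster mean."""
    if J > Z.shape[0]:
        raise ValueError(f"J={J} exceeds number of spots {Z.shape[0]}")
    for attempt in range(5):
        km = KMeans(n_clusters=J, n_init=20, random_state=seed + attempt, init="k-means++")
        labels = km.fit_predict(Z)
        counts = np.bincount(labels, minlength=J)
        if np.all(counts > 0):
            # recompute as exact means of assigned samples
            cents = np.vstack([Z[labels == j].mean(axis=0) for j in range(J)])
            return cents
    raise RuntimeError(f"k-means produced an empty cluster in 5 attempts (J={J})")


def _pairwise_sq_dists(Z, centroids):
    """Squared Euclidean distances, tensor-aware."""
    if isinstance(Z, Tensor) or isinstance(centroids, Tensor):
        Z = Z if isinstance(Z, Tensor) else Tensor(Z)
        C = centroids if isinstance(centroids, Tensor) else Tensor(centroids)
        zz = (Z**2).sum(axis=1, keepdims=True)  # (n,1)
        cc = (C**2).sum(axis=1, keepdims=True).T  # (1,J)
        return zz + cc - 2.0 * (Z @ C.T)
    d = (Z**2).sum(axis=1)[:, None] + (centroids**2).sum(axis=1)[None, :]
    return d - 2.0 * Z @ centroids.T


def soft_assign(Z, centroids):
    """Student-t kernel q_ij = (1 + ||z_i - phi_j||^2)^-1, row-normalized."""
    d2 = _pairwise_sq_dists(Z, centroids)
    if isinstance(d2, Tensor):
        num = (d2 + 1.0) ** -1.0
        return num / num.sum(axis=1, keepdims=True)
    d2 = np.maximum(d2, 0.0)
    num = 1.0 / (1.0 + d2)
    return num / num.sum(axis=1, keepdims=True)


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened target p_ij = (q_ij^2 / f_j) / sum_j' (q_ij'^2 / f_j'),
    with f_j the per-cluster total soft assignment."""
    Q = np.asarray(Q, dtype=float)
    f = Q.sum(axis=0)
    w = Q**2 / f[None, :]
    return w / w.sum(axis=1, keepdims=True)


def loss_dec(P, Q):
    """KL(P || Q) summed over spots and clusters; P is a constant target."""
    if isinstance(Q, Tensor):
        P = np.asarray(P.data if isinstance(P, Tensor) else P, dtype=float)
        Pn = np.where(P > 0, P, 1.0)  # 0 log 0 := 0
        logP = np.where(P > 0, np.log(Pn), 0.0)
        return (Tensor(P) * (Tensor(logP) - log(Q + 1e-300))).sum()
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"shape mismatch {P.shape} vs {Q.shape}")
    mask = P > 0
    terms = np.zeros_like(P)
    terms[mask] = P[mask] * (np.log(P[mask]) - np.log(Q[mask]))
    return float(terms.sum())
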