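"""Cross-slice mutual-nearest-neighbor anchoring and the readout triplet loss.

Anchors are spot pairs from different slices that appear in each other's
cosine nearest-neighbor sets.  For each anchor, the alpha most similar
cross-slice partners are averaged into a positive readout and alpha
random non-neighbors into a negative readout; a margin loss pulls
anchor-positive pairs together and pushes anchor-negative pairs apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._autograd import Tensor, relu, spmm

__all__ = [
    "TripletSet",
    "find_mnn_anchors",
    "readout_positive",
    "sample_negative_readout",
    "build_triplet_set",
    "loss_triplet",
]


@dataclass
class TripletSet:
    anchors: np.ndarray  # (N_tri,) anchor spot indices
    pos_members: list[np.ndarray]  # per anchor, indices averaged into z+
    neg_members: list[np.ndarray]  # per anchor, indices averaged into z-
    alpha: int = 2
    tau: float = 1.0
    pos_agg: sp.csr_matrix | None = field(default=None, repr=False)
    neg_agg: sp.csr_matrix | None = field(default=None, repr=False)

    @property
    def n_triplets(self) -> int:
        return len(self.anchors)


def _normalize_rows(Z: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return Z / norms


def find_mnn_anchors(
    Z: np.ndarray, slice_of: np.ndarray, nn_size: int = 50
) -> list[tuple[int, int]]:
    """Mutual cosine nearest neighbors across every slice pair.

    Returns global-index pairs (i, j) with slice(i) < slice(j); pair kept
    iff j is in i's top-`nn_size` cross-slice neighbors and vice versa.
    """
    slice_of = np.asarray(slice_of)
    slices = np.unique(slice_of)
    if len(slices) < 2:
        warnings.warn("fewer than two slices: no MNN anchors", stacklevel=2)
        return []
    U = _normalize_rows(np.asarray(Z, dtype=float))
    pairs: list[tuple[int, int]] = []
    for ai in range(len(slices)):
        for bi in range(ai + 1, len(slices)):
            idx_a = np.where(slice_of == slices[ai])[0]
            idx_b = np.where(slice_of == slices[bi])[0]
            k = min(nn_size, len(idx_a), len(idx_b))
            S = U[idx_a] @ U[idx_b].T  # cosine similarities
            top_ab = np.argpartition(-S, kth=k - 1, axis=1)[:, :k]
            top_ba = np.argpartition(-S.T, kth=k - 1, axis=1)[:, :k]
            in_ab = np.zeros(S.shape, dtype=bool)
            in_ab[np.arange(len(idx_a))[:, None], top_ab] = True
            in_ba = np.zeros(S.T.shape, dtype=bool)
            in_ba[np.arange(len(idx_b))[:, None], top_ba] = True
            mutual = in_ab & in_ba.T
            for a_loc, b_loc in zip(*np.nonzero(mutual)):
                pairs.append((int(idx_a[a_loc]), int(idx_b[b_loc])))
    return pairs


def readout_positive(
    Z: np.ndarray, anchor: int, cross_candidates: np.ndarray, alpha: int = 2
) -> np.ndarray:
    """Mean embedding of the alpha most cosine-similar cross-slice candidates."""
    members = _top_alpha_members(Z, anchor, cross_candidates, alpha)
    return Z[members].mean(axis=0)


def _top_alpha_members(Z, anchor, cross_candidates, alpha) -> np.ndarray:
    cross_candidates = np.asarray(cross_candidates, dtype=int)
    if cross_candidates.size == 0:
        raise ValueError("positive candidate set is empty")
    if cross_candidates.size < alpha:
        warnings.warn(
            f"anchor {anchor}: only {cross_candidates.size} positive candidates "
            f"for alpha={alpha}; using all",
            stacklevel=3,
        )
        return cross_candidates
    U = _normalize_rows(Z[cross_candidates])
    u_anchor = Z[anchor] / (np.linalg.norm(Z[anchor]) or 1.0)
    sims = U @ u_anchor
    order = np.lexsort((cross_candidates, -sims))
    return cross_candidates[order[:alpha]]


def sample_negative_readout(
    Z: np.ndarray,
    anchor: int,
    excluded: set[int] | np.ndarray,
    alpha: int,
    seed: int,
) -> np.ndarray:
    """Mean embedding of alpha uniform draws outside the excluded set."""
    members = _negative_members(Z.shape[0], anchor, excluded, alpha,
                                np.random.Generator(np.random.PCG64(seed)))
    return Z[members].mean(axis=0)


def _negative_members(n, anchor, excluded, alpha, rng) -> np.ndarray:
    excluded = set(int(e) for e in np.asarray(list(excluded)).ravel()) | {int(anchor)}
    pool = np.array([i for i in range(n) if i not in excluded], dtype=int)
    if pool.size == 0:
        raise ValueError("no negative candidates available")
    if pool.size < alpha:
        warnings.warn(
            f"negative pool ({pool.size}) smaller than alpha={alpha}; using all",
            stacklevel=3,
        )
        return pool
    return rng.choice(pool, size=alpha, replace=False)


def build_triplet_set(
    Z: np.ndarray,
    slice_of: np.ndarray,
    graph: sp.spmatrix | None,
    alpha: int = 2,
    tau: float = 1.0,
    nn_size: int = 50,
    seed: int = 0,
) -> TripletSet:
    """Anchors + positive/negative membership from the current embedding.

    The per-anchor index sets are frozen into sparse aggregation matrices so
    the training loss can recompute readouts from the live embedding.
    """
    pairs = find_mnn_anchors(Z, slice_of, nn_size=nn_size)
    n = Z.shape[0]
    partners: dict[int, list[int]] = {}
    for i, j in pairs:
        partners.setdefault(i, []).append(j)
        partners.setdefault(j, []).append(i)

    graph_csr = sp.csr_matrix(graph) if graph is not None else None
    rng = np.random.Generator(np.random.PCG64(seed))
    anchors, pos_members, neg_members = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for anchor in sorted(partners):
            cands = np.asarray(partners[anchor], dtype=int)
            pos = _top_alpha_members(Z, anchor, cands, alpha)
            intra = (
                graph_csr[anchor].indices if graph_csr is not None else np.empty(0, dtype=int)
            )
            excluded = set(pos.tolist()) | set(int(x) for x in intra)
            neg = _negative_members(n, anchor, excluded, alpha, rng)
            anchors.append(anchor)
            pos_members.append(pos)
            neg_members.append(neg)

    ts = TripletSet(
        anchors=np.asarray(anchors, dtype=int),
        pos_members=pos_members,
        neg_members=neg_members,
        alpha=alpha,
        tau=tau,
    )
    ts.pos_agg = _aggregation_matrix(pos_members, n)
    ts.neg_agg = _aggregation_matrix(neg_members, n)
    return ts


def _aggregation_matrix(member_lists: list[np.ndarray], n: int) -> sp.csr_matrix:
    rows, cols, vals = [], [], []
    for r, members in enumerate(member_lists):
        w = 1.0 / len(members)
        for m in members:
            rows.append(r)
            cols.append(int(m))
            vals.append(w)
    return sp.csr_matrix((vals, (rows, cols)), shape=(len(member_lists), n))


def loss_triplet(Z, anchors, positives, negatives, tau: float = 1.0):
    """(1/N) sum max(||z - z+||^2 - ||z - z-||^2 + tau, 0). Tensor-aware."""
    anchors = np.asarray(anchors, dtype=int)
    if anchors.size == 0:
        warnings.warn("no triplets: loss is 0", stacklevel=2)
        return 0.0
    if isinstance(Z, Tensor):
        Za = Z[anchors]
        pos = positives if isinstance(positives, Tensor) else Tensor(positives)
        neg = negatives if isinstance(negatives, Tensor) else Tensor(negatives)
        d_pos = ((Za - pos) ** 2).sum(axis=1)
        d_neg = ((Za - neg) ** 2).sum(axis=1)
        return relu(d_pos - d_neg + tau).mean()
    Za = Z[anchors]
    d_pos = ((Za - positives) ** 2).sum(axis=1)
    d_neg = ((Za - negatives) ** 2).sum(axis=1)
    return float(np.maximum(d_pos - d_neg + tau, 0.0).mean())


def triplet_loss_from_set(Z: Tensor, ts: TripletSet):
    """Training-path loss: readouts recomputed from the live embedding."""
    if ts.n_triplets == 0:
        return Tensor(0.0)
    pos = spmm(ts.pos_agg, Z)
    neg = spmm(ts.neg_agg, Z)
    return loss_triplet(Z, ts.anchors, pos, neg, tau=ts.tau)


def export_anchors(pairs: list[tuple[int, int]], slice_of: np.ndarray, path):
    with open(path, "w") as fh:
        fh.write("spot_i\tslice_i\tspot_j\tslice_j\n")
        for i, j in pairs:
            fh.write(f"{i}\t{slice_of[i]}\t{j}\t{slice_of[j]}\n")
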