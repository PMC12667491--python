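"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (and sklearn):
pair enumeration for Rand-type indices, entropy-by-hand for the
information-theoretic scores, power iteration for spectral bounds.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pair_counts_oracle(a, b):
    """TP/TN/FP/FN by literal enumeration of all unordered sample pairs."""
    tp = tn = fp = fn = 0
    for i, j in itertools.combinations(range(len(a)), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        if same_a and same_b:
            tp += 1
        elif not same_a and not same_b:
            tn += 1
        elif same_a and not same_b:
            fn += 1
        else:
            fp += 1
    return tp, tn, fp, fn


def ari_oracle(a, b) -> float:
    """Hubert-Arabie ARI from enumerated pair counts."""
    tp, tn, fp, fn = pair_counts_oracle(a, b)
    n_pairs = tp + tn + fp + fn
    sum_a = tp + fn  # pairs together in a
    sum_b = tp + fp  # pairs together in b
    expected = sum_a * sum_b / n_pairs
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (tp - expected) / (max_index - expected)


def _entropy(labels) -> float:
    labels = np.asarray(labels)
    n = labels.size
    h = 0.0
    for v in set(labels.tolist()):
        p = np.sum(labels == v) / n
        h -= p * math.log(p)
    return h


def _mutual_information(a, b) -> float:
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    mi = 0.0
    for u in set(a.tolist()):
        for v in set(b.tolist()):
            nij = np.sum((a == u) & (b == v))
            if nij == 0:
                continue
            pij = nij / n
            mi += pij * math.log(pij / ((np.sum(a == u) / n) * (np.sum(b == v) / n)))
    return mi


def nmi_oracle(a, b) -> float:
    """Arithmetic-normalized mutual information by hand-computed entropies."""
    mi = _mutual_information(a, b)
    ha, hb = _entropy(a), _entropy(b)
    denom = 0.5 * (ha + hb)
    if denom == 0:
        return 1.0
    return mi / denom


def _expected_mi(a, b) -> float:
    """Exact expected MI under the permutation model (hypergeometric sums)."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    a_vals = sorted(set(a.tolist()))
    b_vals = sorted(set(b.tolist()))
    ai = [int(np.sum(a == u)) for u in a_vals]
    bj = [int(np.sum(b == v)) for v in b_vals]
    lgam = math.lgamma
    emi = 0.0
    for x in ai:
        for y in bj:
            lo = max(1, x + y - n)
            hi = min(x, y)
            for nij in range(lo, hi + 1):
                term1 = nij / n * math.log(n * nij / (x * y))
                log_term2 = (
                    lgam(x + 1) + lgam(y + 1) + lgam(n - x + 1) + lgam(n - y + 1)
                    - lgam(n + 1) - lgam(nij + 1) - lgam(x - nij + 1)
                    - lgam(y - nij + 1) - lgam(n - x - y + nij + 1)
                )
                emi += term1 * math.exp(log_term2)
    return emi


def ami_oracle(a, b) -> float:
    """Adjusted mutual information, arithmetic normalization."""
    mi = _mutual_information(a, b)
    emi = _expected_mi(a, b)
    ha, hb = _entropy(a), _entropy(b)
    normalizer = 0.5 * (ha + hb)
    denom = normalizer - emi
    if denom == 0:
        return 1.0
    if denom < 0:
        denom = min(denom, -np.finfo(float).eps)
    return (mi - emi) / denom


def homogeneity_completeness_v_oracle(truth, pred):
    """1 - H(truth|pred)/H(truth), the symmetric dual, and their harmonic mean."""
    truth, pred = np.asarray(truth), np.asarray(pred)
    n = truth.size

    def cond_entropy(u, v):
        h = 0.0
        for vv in set(v.tolist()):
            sel = v == vv
            nv = sel.sum()
            for uu in set(u[sel].tolist()):
                nuv = np.sum(sel & (u == uu))
                h -= nuv / n * math.log(nuv / nv)
        return h

    h_truth, h_pred = _entropy(truth), _entropy(pred)
    hom = 1.0 if h_truth == 0 else 1.0 - cond_entropy(truth, pred) / h_truth
    com = 1.0 if h_pred == 0 else 1.0 - cond_entropy(pred, truth) / h_pred
    v = 0.0 if hom + com == 0 else 2 * hom * com / (hom + com)
    return hom, com, v


def top_eigenvalue_oracle(M: np.ndarray, iters: int = 2000, seed: int = 0) -> float:
    """Largest |eigenvalue| of a symmetric matrix by power iteration."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=M.shape[0])
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(iters):
        w = M @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            return 0.0
        v = w / norm
        lam = float(v @ M @ v)
    return abs(lam)
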