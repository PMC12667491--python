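"""Final clustering of the latent embedding and all evaluation metrics.

Clustering is model-based (Gaussian mixture EM with shared full
covariance and k-means initialization).  Metrics: adjusted Rand index
(standard Hubert-Arabie form and the pair-count variant), NMI/AMI and
their mean, homogeneity/completeness/V-measure, and perplexity-calibrated
local inverse Simpson's indices for batch mixing (iLISI) and domain
purity (cLISI).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
from sklearn import metrics as skm
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "MetricsReport",
    "cluster_embedding",
    "ari",
    "acc",
    "v_measure",
    "lisi",
    "evaluate_embedding",
]


@dataclass
class MetricsReport:
    ari: float | None = None
    ari_paper_form: float | None = None
    nmi: float | None = None
    ami: float | None = None
    acc: float | None = None
    hom: float | None = None
    com: float | None = None
    v_measure: float | None = None
    ilisi_mean: float | None = None
    clisi_mean: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def cluster_embedding(Z: np.ndarray, n_domains: int, seed: int = 0) -> np.ndarray:
    """EM Gaussian mixture (shared full covariance, k-means init, 10 restarts)."""
    if n_domains < 2:
        raise ValueError("n_domains must be >= 2")
    reg = 1e-6
    for _ in range(4):
        try:
            gmm = GaussianMixture(
                n_components=n_domains,
                covariance_type="tied",
                n_init=10,
                init_params="kmeans",
                random_state=seed,
                reg_covar=reg,
                max_iter=300,
            )
            return gmm.fit_predict(Z)
        except (ValueError, np.linalg.LinAlgError):
            reg *= 100.0
    raise RuntimeError("Gaussian mixture EM failed even with ridge regularization")


def _check_labels(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least two samples")
    return a, b


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, float]:
    """TP/FP/FN/TN over all unordered sample pairs, from the contingency table."""
    cont = skm.cluster.contingency_matrix(a, b)
    n = a.size
    tot = n * (n - 1) / 2.0
    same_both = (cont * (cont - 1) / 2.0).sum()
    ai = cont.sum(axis=1)
    bj = cont.sum(axis=0)
    same_a = (ai * (ai - 1) / 2.0).sum()
    same_b = (bj * (bj - 1) / 2.0).sum()
    tp = same_both
    fp = same_b - same_both
    fn = same_a - same_both
    tn = tot - tp - fp - fn
    return tp, tn, fp, fn


def ari(a, b, form: str = "standard") -> float:
    """Adjusted Rand index.

    ``standard``: Hubert-Arabie chance-adjusted form.  ``paper``: the
    pair-count form (TP + TN - E) / (TP + TN + FP + FN - E) with
    E = ((TP+FP)(TP+FN) + (FN+TN)(FP+TN)) / (TP+TN+FP+FN).
    """
    a, b = _check_labels(a, b)
    if form == "standard":
        return float(skm.adjusted_rand_score(a, b))
    if form != "paper":
        raise ValueError(f"unknown ARI form {form!r}")
    tp, tn, fp, fn = _pair_counts(a, b)
    total = tp + tn + fp + fn
    e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / total
    denom = total - e
    if denom == 0:
        return 1.0
    return float((tp + tn - e) / denom)


def acc(a, b) -> float:
    """Mean of NMI and AMI (both with arithmetic normalization)."""
    a, b = _check_labels(a, b)
    nmi = skm.normalized_mutual_info_score(a, b, average_method="arithmetic")
    ami = skm.adjusted_mutual_info_score(a, b, average_method="arithmetic")
    return float((nmi + ami) / 2.0)


def v_measure(a, b) -> tuple[float, float, float]:
    """(homogeneity, completeness, V) with the 0/0 := 1 degenerate convention."""
    a, b = _check_labels(a, b)
    hom, com, v = skm.homogeneity_completeness_v_measure(a, b)
    return float(hom), float(com), float(v)


def lisi(
    embedding: np.ndarray, categories, perplexity: float = 30.0
) -> np.ndarray:
    """Per-spot local inverse Simpson's index of `categories`.

    Gaussian-kernel weights over each spot's 3*perplexity nearest
    neighbors are calibrated (binary search on the bandwidth) to the
    target perplexity; the score is the inverse Simpson's index of the
    weighted category distribution.  1 = single category locally; the
    number of categories = perfect local mixing.
    """
    Z = np.asarray(embedding, dtype=float)
    cats = np.unique(np.asarray(categories), return_inverse=True)[1]
    n = Z.shape[0]
    k = int(3 * perplexity)
    if k >= n:
        warnings.warn(
            f"3*perplexity={k} >= n={n}; reducing neighborhood to n-1", stacklevel=2
        )
        k = n - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z)
    dist, idx = nn.kneighbors(Z)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    log_perp = np.log(min(perplexity, k))
    n_cat = cats.max() + 1
    out = np.empty(n)
    for i in range(n):
        p = _calibrated_weights(dist[i] ** 2, log_perp)
        sums = np.bincount(cats[idx[i]], weights=p, minlength=n_cat)
        simpson = float((sums**2).sum())
        out[i] = 1.0 / max(simpson, 1e-300)
    return out


def _calibrated_weights(d2: np.ndarray, log_perp: float, tol: float = 1e-5) -> np.ndarray:
    """Binary search the precision beta so entropy(p) matches log(perplexity)."""
    beta, lo, hi = 1.0 / (np.mean(d2) + 1e-12), 0.0, np.inf
    d2 = d2 - d2.min()
    for _ in range(64):
        w = np.exp(-beta * d2)
        sw = w.sum()
        if sw <= 0:
            p = np.full_like(d2, 1.0 / d2.size)
            break
        p = w / sw
        h = -(p * np.log(np.maximum(p, 1e-300))).sum()
        if abs(h - log_perp) < tol:
            break
        if h > log_perp:
            lo = beta
            beta = beta * 2 if not np.isfinite(hi) else (beta + hi) / 2
        else:
            hi = beta
            beta = (lo + beta) / 2
    return p


def evaluate_embedding(
    Z: np.ndarray,
    pred_labels: np.ndarray,
    true_labels: np.ndarray | None = None,
    slice_labels: np.ndarray | None = None,
    perplexity: float = 30.0,
) -> MetricsReport:
    """Assemble the full report; label-dependent metrics only when truth given."""
    report = MetricsReport()
    if true_labels is not None:
        report.ari = ari(true_labels, pred_labels, form="standard")
        report.ari_paper_form = ari(true_labels, pred_labels, form="paper")
        report.nmi = float(
            skm.normalized_mutual_info_score(true_labels, pred_labels, average_method="arithmetic")
        )
        report.ami = float(
            skm.adjusted_mutual_info_score(true_labels, pred_labels, average_method="arithmetic")
        )
        report.acc = acc(true_labels, pred_labels)
        report.hom, report.com, report.v_measure = v_measure(true_labels, pred_labels)
    if slice_labels is not None:
        report.ilisi_mean = float(np.mean(lisi(Z, slice_labels, perplexity=perplexity)))
    domain_for_clisi = true_labels if true_labels is not None else pred_labels
    report.clisi_mean = float(np.mean(lisi(Z, domain_for_clisi, perplexity=perplexity)))
    return report
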