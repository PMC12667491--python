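"""Downstream utilities: 3D stacking, expression denoising, marker ranking."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ranksums

from .data_io import GeneSpace, SliceData

__all__ = ["Stack3D", "center_align_stack", "denoise_expression", "rank_markers"]


@dataclass
class Stack3D:
    coords3d: np.ndarray  # (n, 3)
    z_spacing: float
    slice_order: list[str]


def center_align_stack(slices: list[SliceData], z_spacing: float = 1.0) -> Stack3D:
    """Translate each slice so its 2D centroid is at the origin; stack along z.

    No rotation or scaling is applied; z = slice_index * z_spacing.
    Idempotent: re-aligning aligned coordinates is a no-op.
    """
    if not slices:
        raise ValueError("need at least one slice")
    blocks = []
    for i, s in enumerate(slices):
        centered = s.coords - s.coords.mean(axis=0, keepdims=True)
        z = np.full((centered.shape[0], 1), i * z_spacing)
        blocks.append(np.hstack([centered, z]))
    return Stack3D(
        coords3d=np.vstack(blocks),
        z_spacing=z_spacing,
        slice_order=[s.slice_id for s in slices],
    )


def denoise_expression(X_tilde: np.ndarray, gene_space: GeneSpace) -> np.ndarray:
    """Inverse-PCA of the decoder output back to HVG space, clipped at 0."""
    if gene_space is None or gene_space.pca_components is None:
        raise ValueError("PCA basis missing; preprocessing must store a GeneSpace")
    X_tilde = np.asarray(X_tilde, dtype=float)
    if X_tilde.shape[1] != gene_space.pca_components.shape[0]:
        raise ValueError(
            f"decoder output has {X_tilde.shape[1]} components but basis has "
            f"{gene_space.pca_components.shape[0]}"
        )
    expr = X_tilde @ gene_space.pca_components + gene_space.pca_mean
    return np.clip(expr, 0.0, None)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def rank_markers(
    expression: np.ndarray,
    labels: np.ndarray,
    gene_names: list[str] | None = None,
    top_n: int = 25,
) -> pd.DataFrame:
    """Per-domain Wilcoxon rank-sum markers (in-domain vs rest).

    Returns a tidy table (domain, gene, statistic, log2fc, pval, qval, rank)
    with BH-adjusted p-values, keeping the `top_n` genes per domain ranked
    by the rank-sum statistic.  Domains with fewer than 3 spots are skipped.
    """
    expression = np.asarray(expression, dtype=float)
    labels = np.asarray(labels)
    n, g = expression.shape
    if gene_names is None:
        gene_names = [f"gene_{i}" for i in range(g)]
    rows = []
    for dom in np.unique(labels):
        in_dom = labels == dom
        if in_dom.sum() < 3:
            warnings.warn(f"domain {dom!r} has fewer than 3 spots; skipped", stacklevel=2)
            continue
        stats = np.empty(g)
        pvals = np.empty(g)
        for j in range(g):
            res = ranksums(expression[in_dom, j], expression[~in_dom, j])
            stats[j], pvals[j] = res.statistic, res.pvalue
        qvals = _bh_adjust(pvals)
        mean_in = expression[in_dom].mean(axis=0)
        mean_out = expression[~in_dom].mean(axis=0)
        log2fc = np.log2((mean_in + 1e-9) / (mean_out + 1e-9))
        order = np.argsort(-stats)[:top_n]
        for r, j in enumerate(order):
            rows.append(
                {
                    "domain": dom,
                    "gene": gene_names[j],
                    "statistic": stats[j],
                    "log2fc": log2fc[j],
                    "pval": pvals[j],
                    "qval": qvals[j],
                    "rank": r + 1,
                }
            )
    return pd.DataFrame(rows)
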