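"""Input parsing and the expression preprocessing chain.

Per-slice count matrices with 2D spot coordinates are read from MTX
bundles, dense CSVs, or an AnnData/h5ad container, then pushed through
gene filtering -> library-size normalization -> log1p -> highly-variable
gene selection -> PCA, producing the joint reduced matrix consumed by the
model.  Slices are concatenated in input order and spot order within a
slice is preserved; every downstream module relies on that indexing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.decomposition import PCA

__all__ = [
    "SliceData",
    "GeneSpace",
    "JointDataset",
    "StructuralError",
    "load_slices",
    "filter_genes",
    "normalize_log_hvg",
    "reduce_pca",
    "build_joint_matrix",
]


class StructuralError(ValueError):
    """Raised when input files disagree with each other structurally."""


@dataclass
class SliceData:
    """One tissue section: counts, spot coordinates and identifiers."""

    counts: np.ndarray  # (spots, genes) non-negative integers
    coords: np.ndarray  # (spots, 2)
    slice_id: str
    gene_names: list[str]
    spot_ids: list[str]
    labels: np.ndarray | None = None  # optional per-spot domain annotation

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.coords.shape[0] != self.counts.shape[0]:
            raise StructuralError(
                f"slice {self.slice_id!r}: {self.counts.shape[0]} spots in the "
                f"matrix but {self.coords.shape[0]} coordinate rows"
            )
        if len(self.gene_names) != self.counts.shape[1]:
            raise StructuralError(
                f"slice {self.slice_id!r}: gene name count does not match matrix columns"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError(f"slice {self.slice_id!r}: duplicate gene names")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]


@dataclass
class GeneSpace:
    """Retained HVG list plus the PCA basis, kept for inverse mapping."""

    genes: list[str]
    pca_mean: np.ndarray  # (n_hvg,)
    pca_components: np.ndarray  # (n_components, n_hvg)

    def to_json(self) -> str:
        return json.dumps(
            {
                "genes": self.genes,
                "pca_mean": self.pca_mean.tolist(),
                "pca_components": self.pca_components.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GeneSpace":
        d = json.loads(text)
        return cls(
            genes=list(d["genes"]),
            pca_mean=np.asarray(d["pca_mean"], dtype=float),
            pca_components=np.asarray(d["pca_components"], dtype=float),
        )


@dataclass
class JointDataset:
    """Concatenated reduced expression plus graph and slice membership."""

    X: np.ndarray  # (n, m) PCA-reduced expression
    slice_of: np.ndarray  # (n,) spot -> slice index
    gene_space: GeneSpace
    A: sp.csr_matrix | None = None  # block-diagonal binary adjacency
    coords: np.ndarray | None = None  # (n, 2) concatenated coordinates
    spot_ids: list[str] = field(default_factory=list)
    slice_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def validate(self):
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite entries")
        if self.A is not None:
            if (self.A != self.A.T).nnz != 0:
                raise ValueError("A must be symmetric")
            rows, cols = self.A.nonzero()
            if np.any(self.slice_of[rows] != self.slice_of[cols]):
                raise ValueError("A links spots from different slices")


# ---------------------------------------------------------------------------
# loading


def _read_coords_csv(path: Path) -> tuple[np.ndarray, list[str] | None]:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "x" in cols and "y" in cols:
        coords = df[[cols["x"], cols["y"]]].to_numpy(dtype=float)
        ids = df[cols["spot_id"]].astype(str).tolist() if "spot_id" in cols else None
    else:
        coords = df.iloc[:, -2:].to_numpy(dtype=float)
        ids = None
    return coords, ids


def _load_csv_slice(path: Path, slice_id: str) -> SliceData:
    expr = pd.read_csv(path, index_col=0)
    coords_path = path.with_suffix(".coords.csv")
    if not coords_path.exists():
        raise FileNotFoundError(f"missing coordinates file {coords_path}")
    coords, ids = _read_coords_csv(coords_path)
    return SliceData(
        counts=expr.to_numpy(),
        coords=coords,
        slice_id=slice_id,
        gene_names=[str(g) for g in expr.columns],
        spot_ids=ids or [str(s) for s in expr.index],
    )


def _load_mtx_slice(directory: Path, slice_id: str) -> SliceData:
    mtx = scipy.io.mmread(str(directory / "matrix.mtx"))
    genes = pd.read_csv(directory / "features.tsv", sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    counts = np.asarray(sp.csr_matrix(mtx).todense())
    if counts.shape == (len(genes), len(barcodes)):
        counts = counts.T  # genes x spots on disk (CellRanger layout)
    coords_path = directory / "coords.csv"
    if not coords_path.exists():
        raise FileNotFoundError(f"missing coordinates file {coords_path}")
    coords, _ = _read_coords_csv(coords_path)
    return SliceData(
        counts=counts,
        coords=coords,
        slice_id=slice_id,
        gene_names=genes,
        spot_ids=barcodes,
    )


def _load_h5_slice(path: Path, slice_id: str, coord_keys: tuple[str, str]) -> SliceData:
    import anndata as ad

    adata = ad.read_h5ad(path)
    for key in coord_keys:
        if key not in adata.obs.columns:
            raise FileNotFoundError(
                f"{path}: coordinate column {key!r} not found in obs"
            )
    X = adata.X
    counts = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    coords = adata.obs[list(coord_keys)].to_numpy(dtype=float)
    return SliceData(
        counts=counts,
        coords=coords,
        slice_id=slice_id,
        gene_names=[str(g) for g in adata.var_names],
        spot_ids=[str(s) for s in adata.obs_names],
    )


def load_slices(
    paths: list[str | Path],
    format: str = "csv",
    coord_keys: tuple[str, str] = ("x", "y"),
) -> list[SliceData]:
    """Load one :class:`SliceData` per path, preserving spot order.

    ``csv``: a spots x genes matrix with header gene names and index spot
    ids; coordinates expected at ``<path>.coords.csv``.  ``mtx``: a
    directory with matrix.mtx / features.tsv / barcodes.tsv / coords.csv.
    ``h5container``: an h5ad file with coordinate columns in ``.obs``.
    """
    slices = []
    for i, p in enumerate(paths):
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(p)
        slice_id = p.stem if p.stem != "matrix" else p.parent.name
        if format == "csv":
            slices.append(_load_csv_slice(p, slice_id))
        elif format == "mtx":
            slices.append(_load_mtx_slice(p, slice_id))
        elif format == "h5container":
            slices.append(_load_h5_slice(p, slice_id, coord_keys))
        else:
            raise ValueError(f"unknown format {format!r}")
    seen = {}
    for s in slices:
        if s.slice_id in seen:
            s.slice_id = f"{s.slice_id}_{id(s) % 10_000}"
        seen[s.slice_id] = True
    return slices


# ---------------------------------------------------------------------------
# preprocessing chain


def _intersect_genes(slices: list[SliceData]) -> list[SliceData]:
    common = set(slices[0].gene_names)
    for s in slices[1:]:
        common &= set(s.gene_names)
    if not common:
        raise ValueError("slices share no genes")
    # keep first slice's ordering for determinism
    ordered = [g for g in slices[0].gene_names if g in common]
    out = []
    for s in slices:
        idx = [s.gene_names.index(g) for g in ordered] if s.gene_names != ordered else slice(None)
        out.append(
            SliceData(
                counts=s.counts[:, idx],
                coords=s.coords,
                slice_id=s.slice_id,
                gene_names=list(ordered),
                spot_ids=list(s.spot_ids),
                labels=s.labels,
            )
        )
    return out


def filter_genes(
    slices: list[SliceData], min_spots: int = 50, min_total: int = 10
) -> list[SliceData]:
    """Keep genes expressed in >= min_spots spots AND with total count >= min_total.

    Both thresholds are evaluated on the spot-wise concatenation of all
    slices; the same retained gene set is applied to every slice.
    Idempotent by construction.
    """
    slices = _intersect_genes(slices)
    stacked = np.vstack([s.counts for s in slices])
    n_expressed = (stacked > 0).sum(axis=0)
    totals = stacked.sum(axis=0)
    keep = (n_expressed >= min_spots) & (totals >= min_total)
    if not keep.any():
        raise ValueError(
            f"no genes survive filtering (min_spots={min_spots}, min_total={min_total})"
        )
    kept_names = [g for g, k in zip(slices[0].gene_names, keep) if k]
    return [
        SliceData(
            counts=s.counts[:, keep],
            coords=s.coords,
            slice_id=s.slice_id,
            gene_names=list(kept_names),
            spot_ids=list(s.spot_ids),
            labels=s.labels,
        )
        for s in slices
    ]


def normalize_log_hvg(
    slices: list[SliceData], n_hvg: int = 2000
) -> tuple[np.ndarray, list[str]]:
    """Library-size normalize to the median library, log1p, select HVGs.

    Highly variable genes are ranked by normalized dispersion (dispersion
    z-scored within mean-abundance bins) computed on the concatenated
    normalized data.  Returns the (n, n_hvg) matrix with rows ordered
    slice-by-slice, plus the retained gene names.
    """
    stacked = np.vstack([s.counts for s in slices]).astype(float)
    libs = stacked.sum(axis=1)
    libs[libs == 0] = 1.0
    target = float(np.median(libs))
    norm = stacked / libs[:, None] * target
    logged = np.log1p(norm)

    mean = logged.mean(axis=0)
    var = logged.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)

    n_genes = stacked.shape[1]
    if n_hvg > n_genes:
        warnings.warn(
            f"n_hvg={n_hvg} exceeds available gene count {n_genes}; clamping",
            stacklevel=2,
        )
        n_hvg = n_genes

    n_bins = min(20, max(1, n_genes // 10))
    bins = pd.qcut(mean, q=n_bins, duplicates="drop", labels=False)
    norm_disp = np.zeros_like(dispersion)
    for b in np.unique(bins):
        in_bin = bins == b
        mu_b = dispersion[in_bin].mean()
        sd_b = dispersion[in_bin].std()
        norm_disp[in_bin] = (dispersion[in_bin] - mu_b) / (sd_b if sd_b > 0 else 1.0)
    norm_disp[var == 0] = -np.inf  # constant genes can never be variable

    order = np.argsort(-norm_disp, kind="stable")
    hvg_idx = np.sort(order[:n_hvg])
    genes = [slices[0].gene_names[i] for i in hvg_idx]
    return logged[:, hvg_idx], genes


def reduce_pca(
    E: np.ndarray, n_components: int = 200, seed: int = 0
) -> tuple[np.ndarray, PCA]:
    """Center and project onto the top principal axes; basis returned for
    the inverse transform used by expression denoising."""
    max_comp = min(E.shape) - 1 if min(E.shape) > 1 else 1
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} >= rank bound {max_comp}; reducing",
            stacklevel=2,
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    X = pca.fit_transform(E)
    return X, pca


def build_joint_matrix(
    slices: list[SliceData],
    min_spots: int = 50,
    min_total: int = 10,
    n_hvg: int = 2000,
    n_components: int = 200,
    seed: int = 0,
) -> JointDataset:
    """Full preprocessing chain producing a :class:`JointDataset` (graph unset)."""
    filtered = filter_genes(slices, min_spots=min_spots, min_total=min_total)
    logged, genes = normalize_log_hvg(filtered, n_hvg=n_hvg)
    X, pca = reduce_pca(logged, n_components=n_components, seed=seed)
    slice_of = np.concatenate(
        [np.full(s.n_spots, i, dtype=int) for i, s in enumerate(filtered)]
    )
    gene_space = GeneSpace(
        genes=genes, pca_mean=pca.mean_.copy(), pca_components=pca.components_.copy()
    )
    ds = JointDataset(
        X=X,
        slice_of=slice_of,
        gene_space=gene_space,
        coords=np.vstack([s.coords for s in filtered]),
        spot_ids=[sid for s in filtered for sid in s.spot_ids],
        slice_ids=[s.slice_id for s in filtered],
    )
    ds.validate()
    return ds
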