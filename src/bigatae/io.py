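"""Reading, writing, validation and preprocessing of spatial-transcriptomics slices.

A *slice* is one tissue section: an ``N x D`` spot-by-gene expression matrix
together with 2-D spot coordinates and, optionally, ground-truth spatial-domain
labels. Two physically adjacent sections of the same tissue ("consecutive
slices") are the unit the rest of the package operates on.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.io
import scipy.sparse


class SliceFormatError(ValueError):
    """A slice file could not be parsed or violates a shape invariant."""


@dataclass
class SliceData:
    """One spatial-transcriptomics slice.

    Parameters
    ----------
    expression
        Dense ``(n_spots, n_genes)`` float array, no missing entries.
    coords
        ``(n_spots, 2)`` array of spatial coordinates.
    gene_names
        Unique gene identifiers, one per column of ``expression``.
    spot_ids
        Spot identifiers, one per row; synthesized as zero-padded row
        indices when absent from the source file.
    labels
        Optional per-spot spatial-domain labels (ground truth).
    """

    expression: np.ndarray
    coords: np.ndarray
    gene_names: list[str]
    spot_ids: list[str]
    labels: list | None = None

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n, d = self.expression.shape if self.expression.ndim == 2 else (0, 0)
        if self.expression.ndim != 2 or n < 1 or d < 1:
            raise SliceFormatError(
                f"expression must be a 2-D matrix with N>=1 spots and D>=1 genes, "
                f"got shape {self.expression.shape}"
            )
        if np.isnan(self.expression).any():
            raise SliceFormatError("expression contains missing (NaN) entries")
        if self.coords.shape != (n, 2):
            raise SliceFormatError(
                f"coords must have shape ({n}, 2) to match expression, "
                f"got {self.coords.shape}"
            )
        if len(self.gene_names) != d:
            raise SliceFormatError(
                f"{len(self.gene_names)} gene names for {d} expression columns"
            )
        if len(set(self.gene_names)) != d:
            raise SliceFormatError("gene_names are not unique")
        if len(self.spot_ids) != n:
            raise SliceFormatError(
                f"{len(self.spot_ids)} spot ids for {n} expression rows"
            )
        if self.labels is not None and len(self.labels) != n:
            raise SliceFormatError(f"{len(self.labels)} labels for {n} spots")

    @property
    def n_spots(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(
            X=self.expression.copy(),
            obs=pd.DataFrame(index=pd.Index(self.spot_ids, name="spot")),
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )
        adata.obsm["spatial"] = self.coords.copy()
        if self.labels is not None:
            adata.obs["domain"] = pd.Categorical([str(x) for x in self.labels])
        return adata

    @classmethod
    def from_anndata(cls, adata: ad.AnnData, label_key: str = "domain") -> "SliceData":
        X = adata.X
        if scipy.sparse.issparse(X):
            X = X.toarray()
        if "spatial" not in adata.obsm:
            raise SliceFormatError("AnnData lacks obsm['spatial'] coordinates")
        labels = None
        if label_key in adata.obs:
            labels = list(adata.obs[label_key].astype(str))
        return cls(
            expression=np.asarray(X, dtype=float),
            coords=np.asarray(adata.obsm["spatial"], dtype=float)[:, :2],
            gene_names=list(adata.var_names),
            spot_ids=list(adata.obs_names),
            labels=labels,
        )


def _default_spot_ids(n: int) -> list[str]:
    width = max(1, len(str(n - 1)))
    return [f"spot{i:0{width}d}" for i in range(n)]


def _read_coords_tsv(path: str, n_expected: int) -> np.ndarray:
    try:
        coords = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise SliceFormatError(f"could not parse coordinate file {path}: {exc}") from exc
    if coords.ndim != 2 or coords.shape[1] < 2:
        raise SliceFormatError(
            f"coordinate file {path} must have 2 columns (x, y), got shape {coords.shape}"
        )
    if coords.shape[0] != n_expected:
        raise SliceFormatError(
            f"coordinate file {path} has {coords.shape[0]} rows but expression "
            f"has {n_expected} spots"
        )
    return coords[:, :2]


def read_slice(
    path: str,
    fmt: str | None = None,
    coords_path: str | None = None,
    genes_path: str | None = None,
    barcodes_path: str | None = None,
    label_key: str = "domain",
) -> SliceData:
    """Read one slice from disk.

    Supported formats: ``h5ad`` (AnnData; coordinates under
    ``obsm['spatial']``), ``csv`` (spots x genes with a header row of gene
    names, plus a separate 2-column coordinate TSV), and ``mtx`` (MatrixMarket
    triplet, spots x genes, plus genes/barcodes lists and a coordinate TSV).
    ``fmt`` is inferred from the file extension when omitted.
    """
    if fmt is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        fmt = {"h5ad": "h5ad", "csv": "csv", "tsv": "csv", "mtx": "mtx"}.get(ext)
        if fmt is None:
            raise SliceFormatError(f"cannot infer format from extension of {path}")

    if fmt == "h5ad":
        return SliceData.from_anndata(ad.read_h5ad(path), label_key=label_key)

    if fmt == "csv":
        if coords_path is None:
            raise SliceFormatError("csv format requires a coordinate TSV (coords_path)")
        sep = "\t" if path.lower().endswith(".tsv") else ","
        try:
            df = pd.read_csv(path, sep=sep, header=0, index_col=None)
        except Exception as exc:  # noqa: BLE001
            raise SliceFormatError(f"could not parse expression file {path}: {exc}") from exc
        spot_ids = None
        first = df.columns[0]
        # allow an optional leading spot-id column
        if df[first].dtype == object:
            spot_ids = [str(x) for x in df[first]]
            df = df.drop(columns=[first])
        try:
            expr = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise SliceFormatError(
                f"non-numeric entry in expression file {path}: {exc}"
            ) from exc
        coords = _read_coords_tsv(coords_path, expr.shape[0])
        return SliceData(
            expression=expr,
            coords=coords,
            gene_names=[str(c) for c in df.columns],
            spot_ids=spot_ids or _default_spot_ids(expr.shape[0]),
        )

    if fmt == "mtx":
        if coords_path is None or genes_path is None:
            raise SliceFormatError("mtx format requires coords_path and genes_path")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # noqa: BLE001
            raise SliceFormatError(f"could not parse MTX file {path}: {exc}") from exc
        expr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        genes = [line.strip().split("\t")[0] for line in open(genes_path) if line.strip()]
        if barcodes_path is not None:
            spot_ids = [line.strip() for line in open(barcodes_path) if line.strip()]
        else:
            spot_ids = _default_spot_ids(expr.shape[0])
        coords = _read_coords_tsv(coords_path, expr.shape[0])
        return SliceData(expr, coords, genes, spot_ids)

    raise SliceFormatError(f"unknown format {fmt!r} (expected h5ad, csv or mtx)")


def write_slice(slice_data: SliceData, path: str, fmt: str | None = None) -> None:
    """Write a slice as h5ad, or as CSV expression + ``<stem>_coords.tsv``."""
    if fmt is None:
        fmt = "h5ad" if path.lower().endswith(".h5ad") else "csv"
    if fmt == "h5ad":
        slice_data.to_anndata().write_h5ad(path)
        return
    stem = os.path.splitext(path)[0]
    df = pd.DataFrame(
        slice_data.expression, columns=slice_data.gene_names, index=slice_data.spot_ids
    )
    df.to_csv(path, index=True, index_label="spot")
    # coordinate sidecar: 2-column TSV, no header, one row per spot
    pd.DataFrame(slice_data.coords).to_csv(
        stem + "_coords.tsv", sep="\t", index=False, header=False
    )


def _is_count_like(X: np.ndarray, rtol: float = 1e-6) -> bool:
    """True unless every spot's total is already constant (pre-normalized data)."""
    sums = X.sum(axis=1)
    ref = sums.mean()
    if ref == 0:
        return True
    return not np.allclose(sums, ref, rtol=rtol)


def preprocess_pair(
    target: SliceData,
    adjacent: SliceData,
    n_hvg: int = 3000,
    target_sum: float = 1e4,
) -> tuple[SliceData, SliceData]:
    """Bring two slices into the common feature space the attention layer needs.

    Genes are intersected, counts are total-count normalized per spot
    (skipped when per-spot sums are already constant), ``log(1+x)``
    transformed, and the ``min(n_hvg, |intersection|)`` most variable genes
    are selected *jointly* on the vertical concatenation of both slices
    (seurat-flavor normalized dispersion). Joint selection guarantees both
    outputs share an identical gene panel, which the bipartite attention
    concatenation requires.
    """
    if n_hvg < 1:
        raise ValueError(f"n_hvg must be positive, got {n_hvg}")
    shared = [g for g in target.gene_names if g in set(adjacent.gene_names)]
    if len(shared) == 0:
        raise SliceFormatError("slices share no gene names; cannot build a common panel")
    if len(shared) < 2:
        raise SliceFormatError("slices share fewer than 2 gene names")

    def subset(s: SliceData) -> np.ndarray:
        idx = [s.gene_names.index(g) for g in shared]
        return s.expression[:, idx].copy()

    X_t, X_a = subset(target), subset(adjacent)

    processed = []
    for X in (X_t, X_a):
        if _is_count_like(X):
            sums = X.sum(axis=1, keepdims=True)
            sums[sums == 0] = 1.0
            X = X / sums * target_sum
        processed.append(np.log1p(X))
    X_t, X_a = processed

    n_keep = min(n_hvg, len(shared))
    if n_keep < len(shared):
        joint = ad.AnnData(
            X=np.vstack([X_t, X_a]),
            var=pd.DataFrame(index=pd.Index(shared, name="gene")),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.highly_variable_genes(joint, flavor="seurat", n_top_genes=n_keep)
        keep = np.where(joint.var["highly_variable"].to_numpy())[0]
        X_t, X_a = X_t[:, keep], X_a[:, keep]
        kept_genes = [shared[i] for i in keep]
    else:
        kept_genes = shared

    out_t = SliceData(X_t, target.coords.copy(), kept_genes, list(target.spot_ids), target.labels)
    out_a = SliceData(X_a, adjacent.coords.copy(), kept_genes, list(adjacent.spot_ids), adjacent.labels)
    return out_t, out_a
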