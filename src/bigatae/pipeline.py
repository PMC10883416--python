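"""End-to-end workflow: preprocess -> align -> enhance -> cluster -> evaluate.

The downstream clustering adapter is deliberately generic (PCA, kNN graph,
Louvain/Leiden community detection with a resolution search to reach a
requested cluster count) so raw and enhanced matrices are compared under
identical settings — the fairness the side-by-side report depends on.
"""

from __future__ import annotations

import logging
import os
import random
import time
import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from . import metrics as metrics_mod
from .alignment import binarize_alignment, load_alignment, sinkhorn_alignment
from .io import SliceData, preprocess_pair, read_slice
from .model import BigataeParams, train_bigatae

logger = logging.getLogger("bigatae")


@dataclass
class ClusterSettings:
    method: str = "leiden"  # "louvain" | "leiden"
    n_clusters: int = 4
    n_neighbors: int = 15
    n_pcs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("louvain", "leiden"):
            raise ValueError(f"method must be 'louvain' or 'leiden', got {self.method!r}")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be at least 2")


def pca_embed(X: np.ndarray, n_pcs: int, seed: int = 0) -> np.ndarray:
    """Deterministic PCA embedding used for both clustering and SC/CHI."""
    X = np.asarray(X, dtype=float)
    if np.allclose(X.std(axis=0), 0.0):
        raise ValueError("matrix has zero variance; cannot embed or cluster")
    n_comp = min(n_pcs, X.shape[1], X.shape[0] - 1)
    return PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(X)


def _knn_igraph(emb: np.ndarray, n_neighbors: int) -> ig.Graph:
    k = min(n_neighbors, emb.shape[0] - 1)
    A = kneighbors_graph(emb, n_neighbors=k, mode="connectivity", include_self=False)
    A = A.maximum(A.T)  # symmetrize
    src, dst = A.nonzero()
    keep = src < dst
    return ig.Graph(
        n=emb.shape[0], edges=list(zip(src[keep].tolist(), dst[keep].tolist()))
    )


def _communities(graph: ig.Graph, method: str, resolution: float, seed: int) -> np.ndarray:
    if method == "leiden":
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
    else:
        ig.set_random_number_generator(random.Random(seed))
        part = graph.community_multilevel(resolution=resolution)
    return np.asarray(part.membership)


def cluster_enhanced(
    X: np.ndarray,
    settings: ClusterSettings | None = None,
    return_embedding: bool = False,
):
    """Cluster a spot-by-gene (or enhanced) matrix into a requested number of domains.

    PCA to ``n_pcs`` dimensions, symmetrized kNN graph, then Louvain or
    Leiden community detection with the resolution binary-searched in
    [0.01, 5] (at most 25 halvings) until the community count matches
    ``n_clusters``; if no resolution in the bracket achieves it, the
    nearest achievable count is returned with a warning.
    """
    if settings is None:
        settings = ClusterSettings()
    X = np.asarray(X, dtype=float)
    if X.shape[0] <= settings.n_clusters:
        raise ValueError(
            f"need more spots ({X.shape[0]}) than clusters ({settings.n_clusters})"
        )
    emb = pca_embed(X, settings.n_pcs, settings.seed)
    graph = _knn_igraph(emb, settings.n_neighbors)

    lo, hi = 0.01, 5.0
    best_labels, best_gap = None, None
    labels = None
    for _ in range(25):
        res = 0.5 * (lo + hi)
        labels = _communities(graph, settings.method, res, settings.seed)
        k = labels.max() + 1
        gap = abs(int(k) - settings.n_clusters)
        if best_gap is None or gap < best_gap:
            best_labels, best_gap = labels, gap
        if k == settings.n_clusters:
            break
        if k < settings.n_clusters:
            lo = res
        else:
            hi = res
    if best_gap != 0:
        warnings.warn(
            f"resolution search could not reach {settings.n_clusters} communities; "
            f"returning nearest achievable ({best_labels.max() + 1})",
            stacklevel=2,
        )
    labels = best_labels
    if return_embedding:
        return labels, emb
    return labels


@dataclass
class RunConfig:
    """Configuration for a full enhancement run.

    ``alignment_mode`` is ``"sinkhorn"`` (built-in entropic-OT aligner) or
    ``"precomputed"`` (requires ``alignment_path``, e.g. a PASTE plan saved
    as TSV).
    """

    target_path: str | None = None
    adjacent_path: str | None = None
    alignment_path: str | None = None
    output_dir: str | None = None
    alignment_mode: str = "sinkhorn"
    n_hvg: int = 3000
    binarize_threshold: float = 0.0
    binarize_top_k: int | None = 5
    sinkhorn_epsilon: float = 0.05
    sinkhorn_max_iter: int = 2000
    sinkhorn_tol: float = 1e-8
    sinkhorn_spatial_weight: float = 0.5
    epochs: int = 500
    learning_rate: float = 1e-3
    leaky_slope: float = 0.2
    cluster_method: str = "leiden"
    n_clusters: int = 4
    n_neighbors: int = 15
    n_pcs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alignment_mode not in ("sinkhorn", "precomputed"):
            raise ValueError(
                f"alignment_mode must be 'sinkhorn' or 'precomputed', got {self.alignment_mode!r}"
            )
        if self.alignment_mode == "precomputed" and not self.alignment_path:
            raise ValueError("alignment_mode='precomputed' requires alignment_path")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be at least 2")

    def cluster_settings(self) -> ClusterSettings:
        return ClusterSettings(
            method=self.cluster_method,
            n_clusters=self.n_clusters,
            n_neighbors=self.n_neighbors,
            n_pcs=self.n_pcs,
            seed=self.seed,
        )


@dataclass
class RunReport:
    """Side-by-side metrics for raw and enhanced clustering, plus artifacts."""

    raw_metrics: dict[str, float]
    enhanced_metrics: dict[str, float]
    raw_labels: np.ndarray
    enhanced_labels: np.ndarray
    enhanced: "object"  # EnhancedSlice
    n_edges: int
    timings: dict[str, float] = field(default_factory=dict)

    def as_table(self) -> str:
        names = list(self.raw_metrics)
        lines = ["metric\traw\tenhanced"]
        for name in names:
            lines.append(
                f"{name}\t{self.raw_metrics[name]:.10g}\t{self.enhanced_metrics[name]:.10g}"
            )
        return "\n".join(lines) + "\n"


def run_pipeline(
    cfg: RunConfig,
    target: SliceData | None = None,
    adjacent: SliceData | None = None,
) -> RunReport:
    """Execute the full workflow and return the side-by-side report.

    Slices may be passed in memory (library use) or read from
    ``cfg.target_path`` / ``cfg.adjacent_path``. With labeled data the
    report carries the five label-agreement metrics; otherwise SC and CHI
    on the PCA embedding used for clustering. Input files are never
    mutated; all randomness flows from ``cfg.seed``.
    """
    timings: dict[str, float] = {}

    def _stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                return False

        return _T()

    with _stage("read"):
        if target is None:
            if cfg.target_path is None:
                raise ValueError("no target slice: pass one or set target_path")
            target = read_slice(cfg.target_path)
        if adjacent is None:
            if cfg.adjacent_path is None:
                raise ValueError("no adjacent slice: pass one or set adjacent_path")
            adjacent = read_slice(cfg.adjacent_path)
    logger.info("target %dx%d, adjacent %dx%d", target.n_spots, target.n_genes,
                adjacent.n_spots, adjacent.n_genes)

    with _stage("preprocess"):
        p_target, p_adjacent = preprocess_pair(target, adjacent, n_hvg=cfg.n_hvg)
    logger.info("common gene panel: D=%d", p_target.n_genes)

    with _stage("align"):
        if cfg.alignment_mode == "precomputed":
            plan = load_alignment(cfg.alignment_path, p_target, p_adjacent)
        else:
            plan = sinkhorn_alignment(
                p_target, p_adjacent,
                epsilon=cfg.sinkhorn_epsilon,
                max_iter=cfg.sinkhorn_max_iter,
                tol=cfg.sinkhorn_tol,
                spatial_weight=cfg.sinkhorn_spatial_weight,
            )
        graph = binarize_alignment(plan, cfg.binarize_threshold, cfg.binarize_top_k)
    logger.info("bipartite graph: %d edges", graph.n_edges)

    with _stage("train"):
        params = BigataeParams(
            epochs=cfg.epochs,
            learning_rate=cfg.learning_rate,
            leaky_slope=cfg.leaky_slope,
            seed=cfg.seed,
        )
        enhanced = train_bigatae(p_target, p_adjacent, graph, params)
    if enhanced.loss_history:
        logger.info("loss %g -> %g over %d epochs", enhanced.loss_history[0],
                    enhanced.loss_history[-1], len(enhanced.loss_history))

    settings = cfg.cluster_settings()
    with _stage("cluster"):
        raw_labels, raw_emb = cluster_enhanced(
            p_target.expression, settings, return_embedding=True
        )
        enh_labels, enh_emb = cluster_enhanced(enhanced.z, settings, return_embedding=True)

    with _stage("evaluate"):
        if target.labels is not None:
            raw_m = metrics_mod.evaluate_labels(target.labels, raw_labels)
            enh_m = metrics_mod.evaluate_labels(target.labels, enh_labels)
        else:
            raw_m = metrics_mod.evaluate_embedding(raw_emb, raw_labels)
            enh_m = metrics_mod.evaluate_embedding(enh_emb, enh_labels)

    report = RunReport(raw_m, enh_m, raw_labels, enh_labels, enhanced, graph.n_edges, timings)

    if cfg.output_dir:
        os.makedirs(cfg.output_dir, exist_ok=True)
        with open(os.path.join(cfg.output_dir, "metrics.tsv"), "w") as fh:
            fh.write(report.as_table())
        enhanced_slice = enhanced.to_slice(p_target)
        adata = enhanced_slice.to_anndata()
        adata.layers["preprocessed"] = p_target.expression.copy()
        adata.uns["loss_history"] = np.asarray(enhanced.loss_history)
        adata.obs["raw_cluster"] = [str(x) for x in raw_labels]
        adata.obs["enhanced_cluster"] = [str(x) for x in enh_labels]
        adata.write_h5ad(os.path.join(cfg.output_dir, "enhanced.h5ad"))
        np.savetxt(
            os.path.join(cfg.output_dir, "labels.tsv"),
            np.column_stack([p_target.coords, raw_labels, enh_labels]),
            delimiter="\t", header="x\ty\traw\tenhanced", comments="", fmt="%g",
        )
    return report
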