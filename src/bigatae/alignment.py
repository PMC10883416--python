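"""Spot correspondence between two consecutive slices.

The downstream attention layers need a bipartite graph ``BG(U, V, eps)``
whose edges connect target-slice spots (``U``) to adjacent-slice spots
(``V``). The graph is obtained by binarizing a probabilistic alignment plan
``Pi`` — either one computed externally (e.g. by PASTE's fused
Gromov-Wasserstein solver) and loaded from disk, or one produced by the
built-in expression-cost entropic-OT aligner, a desk-scale stand-in
suitable for synthetic or small real pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SliceData


@dataclass
class AlignmentPlan:
    """Probabilistic spot-correspondence matrix ``Pi`` (n_u x n_v).

    Entries are non-negative; plans from the built-in aligner carry uniform
    OT marginals (rows sum to ``1/n_u``, columns to ``1/n_v``).
    """

    plan: np.ndarray
    source_spot_ids: list[str]
    target_spot_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.plan = np.asarray(self.plan, dtype=float)
        if self.plan.ndim != 2:
            raise ValueError(f"plan must be 2-D, got shape {self.plan.shape}")
        if (self.plan < 0).any():
            i, j = np.argwhere(self.plan < 0)[0]
            raise ValueError(f"negative plan entry at ({i}, {j}): {self.plan[i, j]}")
        if len(self.source_spot_ids) != self.plan.shape[0]:
            raise ValueError("source_spot_ids length does not match plan rows")
        if len(self.target_spot_ids) != self.plan.shape[1]:
            raise ValueError("target_spot_ids length does not match plan columns")

    @property
    def shape(self) -> tuple[int, int]:
        return self.plan.shape


@dataclass(frozen=True)
class BipartiteGraph:
    """Binary bipartite adjacency over target spots U and adjacent spots V.

    A spot may have zero, one or many incident edges; zero-degree target
    spots pass through the auto-encoder unchanged.
    """

    n_u: int
    n_v: int
    edges: frozenset

    def __post_init__(self) -> None:
        if self.n_u < 1 or self.n_v < 1:
            raise ValueError("n_u and n_v must be positive")
        for i, j in self.edges:
            if not (0 <= i < self.n_u and 0 <= j < self.n_v):
                raise ValueError(f"edge ({i}, {j}) out of range for {self.n_u}x{self.n_v}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency_mask(self) -> np.ndarray:
        """Dense boolean (n_u, n_v) mask; True where an edge exists."""
        mask = np.zeros((self.n_u, self.n_v), dtype=bool)
        if self.edges:
            idx = np.array(sorted(self.edges))
            mask[idx[:, 0], idx[:, 1]] = True
        return mask


def _minmax_scale(C: np.ndarray) -> np.ndarray:
    lo, hi = C.min(), C.max()
    if hi > lo:
        return (C - lo) / (hi - lo)
    return np.zeros_like(C)


def _sq_dists(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    sq = (X**2).sum(1)[:, None] + (Y**2).sum(1)[None, :] - 2.0 * X @ Y.T
    return np.maximum(sq, 0.0)


def sinkhorn_alignment(
    target: SliceData,
    adjacent: SliceData,
    epsilon: float = 0.05,
    max_iter: int = 2000,
    tol: float = 1e-8,
    spatial_weight: float = 0.5,
) -> AlignmentPlan:
    """Entropic-OT plan between two slices.

    The cost blends squared Euclidean distances between expression
    profiles and between spatial coordinates, each min-max scaled to
    [0, 1]: ``C = (1 - w) * C_expr + w * C_spatial`` with
    ``w = spatial_weight``. Marginals are uniform. Solved by log-domain
    Sinkhorn iterations, stopping when the worst marginal violation drops
    below ``tol`` or ``max_iter`` is reached (then a non-convergence note
    is recorded in the plan metadata and the plan is still returned).

    The blended cost is a desk-scale stand-in for a full fused slice
    aligner (PASTE): consecutive sections share spatial organization, and
    expression alone is too noisy to define a reliable correspondence
    once per-spot noise is realistic. ``spatial_weight=0`` recovers the
    pure expression-cost plan; it assumes the two slices' coordinates are
    already in a common frame up to a small rigid offset (rotations are a
    full aligner's job).
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    if not (0.0 <= spatial_weight <= 1.0):
        raise ValueError(f"spatial_weight must be in [0, 1], got {spatial_weight}")
    if target.n_genes != adjacent.n_genes:
        raise ValueError(
            "slices must share a common gene space (run preprocess_pair first): "
            f"{target.n_genes} vs {adjacent.n_genes} genes"
        )
    X, Y = target.expression, adjacent.expression
    n_u, n_v = X.shape[0], Y.shape[0]
    C = (1.0 - spatial_weight) * _minmax_scale(_sq_dists(X, Y))
    if spatial_weight > 0:
        C = C + spatial_weight * _minmax_scale(_sq_dists(target.coords, adjacent.coords))

    a = np.full(n_u, 1.0 / n_u)
    b = np.full(n_v, 1.0 / n_v)
    # log-domain Sinkhorn on dual potentials f, g (cost units):
    #   P_ij = exp((f_i + g_j - C_ij) / epsilon)
    f = np.zeros(n_u)
    g = np.zeros(n_v)
    log_a, log_b = np.log(a), np.log(b)
    converged = False
    n_it = 0
    P = np.full((n_u, n_v), 1.0 / (n_u * n_v))
    for n_it in range(1, max_iter + 1):
        f = epsilon * log_a - epsilon * _logsumexp_rows((g[None, :] - C) / epsilon)
        g = epsilon * log_b - epsilon * _logsumexp_rows((f[:, None] - C).T / epsilon)
        P = np.exp((f[:, None] + g[None, :] - C) / epsilon)
        err = max(
            np.abs(P.sum(axis=1) - a).max(),
            np.abs(P.sum(axis=0) - b).max(),
        )
        if err < tol:
            converged = True
            break
    meta = {"converged": converged, "n_iter": n_it, "epsilon": epsilon}
    if not converged:
        meta["warning"] = f"Sinkhorn did not reach tol={tol} in {max_iter} iterations"
    return AlignmentPlan(P, list(target.spot_ids), list(adjacent.spot_ids), meta)


def _logsumexp_rows(M: np.ndarray) -> np.ndarray:
    mx = M.max(axis=1, keepdims=True)
    return (mx + np.log(np.exp(M - mx).sum(axis=1, keepdims=True))).ravel()


def load_alignment(path: str, target: SliceData, adjacent: SliceData) -> AlignmentPlan:
    """Load a precomputed plan from a delimited text file and validate it.

    The file is an ``n_u x n_v`` numeric matrix (TSV/CSV, optional header
    auto-detected). Dimensions are checked against the two slices and
    negative entries rejected.
    """
    sep = "," if path.lower().endswith(".csv") else r"\s+"
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str)
    # header detection: first row non-numeric -> drop it (and a label column)
    def _numeric(row) -> bool:
        try:
            [float(x) for x in row]
            return True
        except (TypeError, ValueError):
            return False

    if not _numeric(raw.iloc[0]):
        raw = raw.iloc[1:]
        if not _numeric(raw.iloc[:, 0]):
            raw = raw.iloc[:, 1:]
    try:
        M = raw.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric entry in alignment file {path}: {exc}") from exc
    if M.shape != (target.n_spots, adjacent.n_spots):
        raise ValueError(
            f"alignment file {path} has shape {M.shape}, expected "
            f"({target.n_spots}, {adjacent.n_spots})"
        )
    return AlignmentPlan(M, list(target.spot_ids), list(adjacent.spot_ids))


def save_alignment(plan: AlignmentPlan, path: str) -> None:
    np.savetxt(path, plan.plan, delimiter="\t", fmt="%.15g")


def binarize_alignment(
    plan: AlignmentPlan,
    threshold: float = 0.0,
    top_k: int | None = None,
) -> BipartiteGraph:
    """Convert a probabilistic plan into the binary bipartite graph.

    Edge ``(i, j)`` exists iff ``Pi_ij > threshold`` (strict), so a
    zero-threshold keeps every entry with nonzero support. Because entropic
    plans are dense, ``top_k`` optionally keeps only each target spot's k
    largest entries (still subject to the threshold); ``top_k=5`` is a
    reasonable setting for dense plans. One-to-many correspondences are
    expected and preserved. An empty graph is legal.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    P = plan.plan
    keep = P > threshold
    if top_k is not None:
        if top_k < 1:
            raise ValueError(f"top_k must be positive, got {top_k}")
        if top_k < P.shape[1]:
            cutoff_idx = np.argpartition(-P, top_k - 1, axis=1)[:, :top_k]
            topk_mask = np.zeros_like(keep)
            np.put_along_axis(topk_mask, cutoff_idx, True, axis=1)
            keep &= topk_mask
    edges = frozenset(zip(*np.nonzero(keep)))
    edges = frozenset((int(i), int(j)) for i, j in edges)
    return BipartiteGraph(n_u=P.shape[0], n_v=P.shape[1], edges=edges)
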