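"""Clustering-evaluation metrics.

Five external (label-agreement) metrics — ARI, NMI, AMI, homogeneity,
completeness — computed from the contingency table, and two internal
metrics — silhouette coefficient and Calinski-Harabasz index — computed
from an embedding. All are implemented directly from their defining
formulas; entropies use natural logarithms, AMI's chance expectation is
taken under the permutation (hypergeometric) model and normalized by
max(H(A), H(B)), and NMI by sqrt(H(A) * H(B)).

Degenerate conventions (where the formulas divide by zero): if both
labelings are single-cluster, NMI and AMI are 1.0; if exactly one is,
they are 0.0. Homogeneity is 1.0 when H(C) = 0 and completeness 1.0 when
H(K) = 0.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.special import gammaln


def _check_pair(truth, predicted) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError(f"label vectors must be equal-length 1-D, got {t.shape} and {p.shape}")
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    return t, p


def contingency(truth, predicted) -> np.ndarray:
    """Contingency table n_ij: rows index truth classes, columns predicted."""
    t, p = _check_pair(truth, predicted)
    _, ti = np.unique(t, return_inverse=True)
    _, pi = np.unique(p, return_inverse=True)
    table = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(table, (ti, pi), 1)
    return table


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def ari(truth, predicted) -> float:
    """Adjusted Rand index from pair counts of the contingency table."""
    table = contingency(truth, predicted)
    n = table.sum()
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    sum_ij = _comb2(table.astype(float)).sum()
    sum_a = _comb2(a.astype(float)).sum()
    sum_b = _comb2(b.astype(float)).sum()
    expected = sum_a * sum_b / _comb2(float(n))
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # both labelings trivial (all-singletons or single-cluster): perfect agreement
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def mutual_information(truth, predicted) -> float:
    """MI(A, B) in nats from the contingency table."""
    table = contingency(truth, predicted).astype(float)
    n = table.sum()
    a = table.sum(axis=1, keepdims=True)
    b = table.sum(axis=0, keepdims=True)
    nz = table > 0
    return float((table[nz] / n * np.log(n * table[nz] / (a @ b)[nz])).sum())


def expected_mutual_information(truth, predicted) -> float:
    """E[MI] under the permutation model (hypergeometric marginals).

    Sums, for each truth/predicted class pair, over all feasible cell
    counts n_ij weighted by the hypergeometric probability of that count.
    Log-gamma arithmetic keeps factorial ratios stable.
    """
    table = contingency(truth, predicted)
    n = int(table.sum())
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    log_n_fact = gammaln(n + 1)
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                term = (nij / n) * math.log(n * nij / (ai * bj))
                log_p = (
                    gammaln(ai + 1)
                    + gammaln(bj + 1)
                    + gammaln(n - ai + 1)
                    + gammaln(n - bj + 1)
                    - log_n_fact
                    - gammaln(nij + 1)
                    - gammaln(ai - nij + 1)
                    - gammaln(bj - nij + 1)
                    - gammaln(n - ai - bj + nij + 1)
                )
                emi += term * math.exp(log_p)
    return emi


def nmi(truth, predicted) -> float:
    """Normalized mutual information MI / sqrt(H(A) H(B))."""
    table = contingency(truth, predicted)
    h_a = _entropy(table.sum(axis=1))
    h_b = _entropy(table.sum(axis=0))
    if h_a == 0.0 and h_b == 0.0:
        return 1.0
    if h_a == 0.0 or h_b == 0.0:
        return 0.0
    return mutual_information(truth, predicted) / math.sqrt(h_a * h_b)


def ami(truth, predicted) -> float:
    """Adjusted mutual information, max-normalized, permutation-model expectation."""
    table = contingency(truth, predicted)
    h_a = _entropy(table.sum(axis=1))
    h_b = _entropy(table.sum(axis=0))
    if h_a == 0.0 and h_b == 0.0:
        return 1.0
    if h_a == 0.0 or h_b == 0.0:
        return 0.0
    mi = mutual_information(truth, predicted)
    emi = expected_mutual_information(truth, predicted)
    denom = max(h_a, h_b) - emi
    if denom == 0.0:
        return 1.0 if mi == emi else 0.0
    return (mi - emi) / denom


def homogeneity(truth, predicted) -> float:
    """1 - H(C|K) / H(C): each cluster contains members of a single class."""
    table = contingency(truth, predicted)
    h_c = _entropy(table.sum(axis=1))
    if h_c == 0.0:
        return 1.0
    h_k = _entropy(table.sum(axis=0))
    h_c_given_k = _joint_entropy(table) - h_k  # H(C|K) = H(C,K) - H(K)
    return 1.0 - h_c_given_k / h_c


def completeness(truth, predicted) -> float:
    """1 - H(K|C) / H(K): all members of a class fall in the same cluster."""
    table = contingency(truth, predicted)
    h_k = _entropy(table.sum(axis=0))
    if h_k == 0.0:
        return 1.0
    h_c = _entropy(table.sum(axis=1))
    h_k_given_c = _joint_entropy(table) - h_c
    return 1.0 - h_k_given_c / h_k


def _joint_entropy(table: np.ndarray) -> float:
    return _entropy(table.ravel())


def silhouette(points, labels) -> float:
    """Mean silhouette coefficient, Euclidean distance.

    For each sample, ``a(i)`` is the mean distance to the other members of
    its own cluster and ``b(i)`` the mean distance to the members of the
    nearest other cluster; the score is ``(b - a) / max(a, b)``. Samples
    in singleton clusters score 0.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be a 2-D (n_samples, n_features) array")
    lab = np.asarray(labels)
    uniq, inv = np.unique(lab, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if uniq.size >= X.shape[0]:
        raise ValueError("silhouette requires fewer clusters than samples")
    # pairwise distances; desk-scale N so dense is fine
    sq = (X**2).sum(1)[:, None] + (X**2).sum(1)[None, :] - 2.0 * X @ X.T
    D = np.sqrt(np.maximum(sq, 0.0))
    n = X.shape[0]
    sizes = np.bincount(inv, minlength=uniq.size)
    # sum of distances from each sample to each cluster
    cluster_sums = np.zeros((n, uniq.size))
    for c in range(uniq.size):
        cluster_sums[:, c] = D[:, inv == c].sum(axis=1)
    scores = np.zeros(n)
    for i in range(n):
        c = inv[i]
        if sizes[c] == 1:
            scores[i] = 0.0
            continue
        a_i = cluster_sums[i, c] / (sizes[c] - 1)
        other = [cluster_sums[i, k] / sizes[k] for k in range(uniq.size) if k != c]
        b_i = min(other)
        scores[i] = (b_i - a_i) / max(a_i, b_i)
    return float(scores.mean())


def calinski_harabasz(points, labels) -> float:
    """Calinski-Harabasz index (B/W) * ((N - K)/(K - 1)).

    B is the size-weighted squared deviation of cluster centroids from the
    global centroid; W the within-cluster squared deviation from each
    centroid. Returns +inf (with a warning) when all points coincide with
    their centroids (W = 0).
    """
    X = np.asarray(points, dtype=float)
    lab = np.asarray(labels)
    uniq, inv = np.unique(lab, return_inverse=True)
    n, k = X.shape[0], uniq.size
    if k < 2:
        raise ValueError("Calinski-Harabasz requires at least 2 clusters")
    if k >= n:
        raise ValueError("Calinski-Harabasz requires fewer clusters than samples")
    global_centroid = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for c in range(k):
        pts = X[inv == c]
        centroid = pts.mean(axis=0)
        B += pts.shape[0] * float(((centroid - global_centroid) ** 2).sum())
        W += float(((pts - centroid) ** 2).sum())
    if W == 0.0:
        warnings.warn("zero within-cluster variance; CHI is infinite", stacklevel=2)
        return float("inf")
    return (B / W) * ((n - k) / (k - 1))


LABEL_METRICS = {
    "ARI": ari,
    "AMI": ami,
    "NMI": nmi,
    "Homo": homogeneity,
    "Comp": completeness,
}


def evaluate_labels(truth, predicted) -> dict[str, float]:
    """All five label-agreement metrics as a flat dict."""
    return {name: fn(truth, predicted) for name, fn in LABEL_METRICS.items()}


def evaluate_embedding(points, labels) -> dict[str, float]:
    """Internal metrics (SC, CHI) on an embedding with predicted labels."""
    return {
        "SC": silhouette(points, labels),
        "CHI": calinski_harabasz(points, labels),
    }


def write_report(metrics: dict[str, float], path: str) -> None:
    """Flat TSV of metric-name <tab> value."""
    with open(path, "w") as fh:
        for name, value in metrics.items():
            fh.write(f"{name}\t{value:.10g}\n")
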