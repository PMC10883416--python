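"""Synthetic consecutive-slice generator.

Emulates a pair of physically adjacent tissue sections sharing layered
spatial-domain structure, in the spirit of cortical-layer annotations:
spots sit on a regular grid, domains are horizontal bands, and each domain
has a disjoint set of marker genes whose log-mean expression is elevated.
The two slices share the domain means; each gets independent Gaussian
noise on the log scale, optional dropout, and the second slice's
coordinates are rigidly shifted. Log-expression is exponentiated and
rounded to non-negative integer counts, since the pipeline's preprocessing
normalizes and re-logs anyway.

Deliberately not modelled: negative-binomial/zero-inflated count realism
and between-slice batch effects (batch correction is not this method's
aim).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SliceData


@dataclass
class SynthConfig:
    """Study conditions for one synthetic slice pair.

    Defaults give 200 spots per slice (20 x 10 grid) in 4 horizontal
    domain bands over 60 genes with 10 markers per domain; noise_sd is set
    at the operating point where single-slice Leiden clustering recovers
    the domains only partially, leaving headroom for cross-slice
    enhancement.
    """

    n_rows: int = 20
    n_cols: int = 10
    n_domains: int = 4
    n_genes: int = 60
    domain_effect: float = 1.0
    noise_sd: float = 0.6
    markers_per_domain: int = 10
    spatial_offset: float = 0.35
    dropout_rate: float = 0.05
    base_log_mean: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.n_domains < 2:
            raise ValueError("need at least 2 spatial domains")
        if self.n_domains > self.n_rows:
            raise ValueError("n_domains cannot exceed n_rows (domains are row bands)")
        if self.markers_per_domain * self.n_domains > self.n_genes:
            raise ValueError(
                "markers_per_domain * n_domains exceeds n_genes; marker sets must be disjoint"
            )
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.noise_sd < 0 or self.domain_effect < 0:
            raise ValueError("noise_sd and domain_effect must be non-negative")

    @property
    def n_spots(self) -> int:
        return self.n_rows * self.n_cols


def _domain_of_rows(n_rows: int, n_domains: int) -> np.ndarray:
    """Band index for each grid row, splitting rows as evenly as possible."""
    return np.floor(np.arange(n_rows) * n_domains / n_rows).astype(int)


def generate_slice_pair(cfg: SynthConfig) -> tuple[SliceData, SliceData]:
    """Generate two consecutive slices sharing domain structure.

    Both slices use the same grid, domain labels and domain log-means;
    only the per-entry noise, dropout and the rigid coordinate offset of
    the second slice differ. Fixed seed gives bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n, d, k = cfg.n_spots, cfg.n_genes, cfg.n_domains

    rows, cols = np.divmod(np.arange(n), cfg.n_cols)
    coords = np.column_stack([cols, rows]).astype(float)
    band = _domain_of_rows(cfg.n_rows, k)
    labels = band[rows]

    # shared gene baselines and disjoint marker blocks
    base = rng.normal(loc=cfg.base_log_mean, scale=0.2, size=d)
    log_mean = np.tile(base, (k, 1))
    for dom in range(k):
        markers = slice(dom * cfg.markers_per_domain, (dom + 1) * cfg.markers_per_domain)
        log_mean[dom, markers] += cfg.domain_effect

    slices = []
    for s in range(2):
        log_expr = log_mean[labels] + rng.normal(0.0, cfg.noise_sd, size=(n, d))
        counts = np.rint(np.exp(log_expr))
        if cfg.dropout_rate > 0:
            counts *= rng.random(size=(n, d)) >= cfg.dropout_rate
        offset = cfg.spatial_offset if s == 1 else 0.0
        slices.append(
            SliceData(
                expression=counts,
                coords=coords + offset,
                gene_names=[f"gene{g:03d}" for g in range(d)],
                spot_ids=[f"s{s + 1}_spot{i:03d}" for i in range(n)],
                labels=[int(x) for x in labels],
            )
        )
    return slices[0], slices[1]
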