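"""Reference taxonomy preparation.

Harmonizes expression matrices between modalities (two-pass z-scoring: each
cell across its genes, then each gene across cells), computes per-type
mean/covariance/proportions for the simulator and, when no dendrogram is
supplied, builds one by average-linkage clustering of per-type means on
correlation distance with node heights min-max scaled to [0, 1] so that
granularity sweeps over heights 0–0.8 are well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "ReferenceTaxonomy",
    "GranularityMap",
    "harmonize_expression",
    "type_statistics",
    "granularity_grouping",
    "build_type_linkage",
    "make_synthetic_taxonomy",
]


def harmonize_expression(E: np.ndarray) -> np.ndarray:
    """Two-pass z-score: per cell (row) across genes, then per gene (column).

    Population (1/n) standard deviation in both passes; zero-variance rows or
    columns are scaled by 1 instead of 0.
    """
    E = np.asarray(E, dtype=np.float64)
    if E.ndim != 2 or E.shape[0] < 2 or E.shape[1] < 2:
        raise ValueError("expression matrix must be 2D with >=2 cells and >=2 genes")
    if not np.all(np.isfinite(E)):
        raise ValueError("expression matrix contains non-finite entries")
    mu_r = E.mean(axis=1, keepdims=True)
    sd_r = E.std(axis=1, keepdims=True)
    sd_r[sd_r == 0] = 1.0
    out = (E - mu_r) / sd_r
    mu_c = out.mean(axis=0, keepdims=True)
    sd_c = out.std(axis=0, keepdims=True)
    sd_c[sd_c == 0] = 1.0
    return (out - mu_c) / sd_c


def type_statistics(
    E_ref: np.ndarray, T_ref: np.ndarray, n_types: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-type mean vectors, sample covariance matrices and proportions.

    ``E_ref`` is rounded to integer counts first (scaled count matrix). A type
    with a single cell has no sample covariance; it falls back to a diagonal
    of the pooled per-gene variance with a warning.
    """
    E = np.round(np.asarray(E_ref, dtype=np.float64))
    T = np.asarray(T_ref, dtype=np.int64).ravel()
    if E.shape[0] != T.shape[0]:
        raise ValueError("label vector length must match cell count")
    k = int(T.max()) + 1 if n_types is None else n_types
    m = E.shape[1]
    mu = np.zeros((k, m))
    sigma = np.zeros((k, m, m))
    pooled_var = E.var(axis=0, ddof=1) if E.shape[0] > 1 else np.ones(m)
    counts = np.bincount(T, minlength=k).astype(float)
    for t in range(k):
        rows = E[T == t]
        if rows.shape[0] == 0:
            continue
        mu[t] = rows.mean(axis=0)
        if rows.shape[0] >= 2:
            sigma[t] = np.cov(rows, rowvar=False, ddof=1)
        else:
            warnings.warn(
                f"type {t} has a single cell; covariance falls back to pooled diagonal"
            )
            sigma[t] = np.diag(pooled_var)
    proportions = counts / counts.sum()
    return mu, sigma, proportions


@dataclass
class GranularityMap:
    """A cut of the type dendrogram: fine type -> group at a given height."""

    height: float
    group_of: np.ndarray  # (k,) int, group id per fine type

    @property
    def n_groups(self) -> int:
        return int(len(np.unique(self.group_of)))


def _check_ultrametric(linkage: np.ndarray) -> None:
    heights = linkage[:, 2]
    if np.any(np.diff(heights) < -1e-9):
        raise ValueError("linkage is not ultrametric (non-monotone merge heights)")


def granularity_grouping(linkage: np.ndarray, height: float) -> GranularityMap:
    """Cut the type dendrogram: two fine types share a group iff their merge
    height is <= ``height``. Height 0 returns the identity mapping."""
    linkage = np.asarray(linkage, dtype=np.float64)
    _check_ultrametric(linkage)
    k = linkage.shape[0] + 1
    if height < 0:
        raise ValueError("height must be non-negative")
    # fcluster with 'distance' uses <= t, matching the merge-height rule
    flat = hierarchy.fcluster(linkage, t=height, criterion="distance")
    # renumber groups by first appearance for determinism
    _, first = np.unique(flat, return_index=True)
    order = {flat[i]: rank for rank, i in enumerate(sorted(first))}
    return GranularityMap(height=height, group_of=np.array([order[f] for f in flat]))


def build_type_linkage(mu: np.ndarray) -> np.ndarray:
    """Average-linkage hierarchy of per-type mean vectors on correlation
    distance, heights min-max scaled to [0, 1]."""
    if mu.shape[0] < 2:
        raise ValueError("need at least two types to build a dendrogram")
    d = pdist(mu, metric="correlation")
    # constant mean vectors have undefined correlation; treat them as
    # maximally distant rather than propagating NaN
    d = np.nan_to_num(d, nan=2.0)
    d = np.clip(d, 0, None)
    Z = hierarchy.linkage(d, method="average")
    hmax = Z[:, 2].max()
    if hmax > 0:
        Z[:, 2] = Z[:, 2] / hmax
    return Z


@dataclass
class ReferenceTaxonomy:
    """Reference cell-type catalogue: expression, labels, per-type statistics
    and an ultrametric dendrogram over the types (heights in [0, 1])."""

    E_ref: np.ndarray  # (n_ref, m) counts
    T_ref: np.ndarray  # (n_ref,) int labels in [0, k)
    type_names: list[str]
    mu: np.ndarray = field(default=None)  # (k, m)
    sigma: np.ndarray = field(default=None)  # (k, m, m)
    proportions: np.ndarray = field(default=None)  # (k,)
    linkage: np.ndarray = field(default=None)  # (k-1, 4)

    def __post_init__(self) -> None:
        self.E_ref = np.asarray(self.E_ref, dtype=np.float64)
        self.T_ref = np.asarray(self.T_ref, dtype=np.int64).ravel()
        k = len(self.type_names)
        if self.mu is None or self.sigma is None or self.proportions is None:
            self.mu, self.sigma, self.proportions = type_statistics(
                self.E_ref, self.T_ref, n_types=k
            )
        if self.linkage is None:
            self.linkage = build_type_linkage(self.mu)
        if not np.isclose(self.proportions.sum(), 1.0):
            raise ValueError("type proportions must sum to 1")

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    @property
    def n_genes(self) -> int:
        return self.E_ref.shape[1]

    def grouping(self, height: float) -> GranularityMap:
        return granularity_grouping(self.linkage, height)


def make_synthetic_taxonomy(
    n_types: int = 6,
    n_genes: int = 20,
    cells_per_type: int = 120,
    *,
    baseline_mean: float = 12.0,
    marker_mean: float = 120.0,
    markers_per_type: int | None = None,
    dispersion: float = 0.35,
    type_scale_range: tuple[float, float] = (0.6, 1.6),
    seed: int = 0,
) -> ReferenceTaxonomy:
    """Construct a synthetic reference taxonomy with well-separated types.

    Each type elevates a disjoint block of marker genes above a shared
    baseline, and types differ in overall mRNA content by a log-spaced factor
    spanning ``type_scale_range`` — mirroring real neural taxonomies, where
    total transcript load varies severalfold between (sub)types and is what
    makes purely density-driven segmentation misplace boundaries. Defaults
    give a few hundred to ~1,000 transcripts per cell, i.e. several spots/μm³
    inside small densely packed somata, the regime hybridization datasets
    report. Per-type covariance is diagonal overdispersion plus a rank-1
    "cell size" component, so genes within a cell are positively correlated
    the way library-size variation correlates real counts. The reference
    matrix is drawn from these Gaussians, rounded and clamped at zero, and
    the dendrogram is rebuilt from the realized means.
    """
    rng = np.random.default_rng(seed)
    if markers_per_type is None:
        markers_per_type = max(1, n_genes // n_types)
    mu = np.full((n_types, n_genes), baseline_mean)
    for t in range(n_types):
        lo = (t * markers_per_type) % n_genes
        idx = (lo + np.arange(markers_per_type)) % n_genes
        mu[t, idx] = marker_mean
    # small jitter so types with wrapped marker blocks are not identical
    mu += rng.uniform(0, 1.5, size=mu.shape)
    scales = np.geomspace(*type_scale_range, n_types)
    mu *= scales[rng.permutation(n_types), None]

    E_rows, T_rows = [], []
    for t in range(n_types):
        sd = dispersion * mu[t] + 1.0
        size_load = 0.15 * mu[t]  # rank-1 library-size factor
        z = rng.standard_normal((cells_per_type, 1))
        eps = rng.standard_normal((cells_per_type, n_genes)) * sd
        rows = mu[t] + z * size_load + eps
        E_rows.append(np.clip(np.round(rows), 0, None))
        T_rows.append(np.full(cells_per_type, t))
    E_ref = np.vstack(E_rows)
    T_ref = np.concatenate(T_rows)
    names = [f"type_{t}" for t in range(n_types)]
    return ReferenceTaxonomy(E_ref=E_ref, T_ref=T_ref, type_names=names)
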