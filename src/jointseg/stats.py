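"""Evaluation and downstream spatial statistics.

* Taxonomy-aware transcript-assignment accuracy: per predicted cell, the
  fraction of its spots whose true cell is that cell or a touching neighbour
  whose true type falls in the same group at a chosen dendrogram cut;
  reported as the mean over cells across a sweep of granularity heights.
* Per-type expression correlation between segmented data and the reference.
* Neighbourhood colocalization of (sub)types via label permutation.
* Spatially differentially expressed genes (spDEGs): within a type, the
  variance of local (cell + 9 nearest same-type neighbours) mean expression
  against a within-type permutation null.

Permutation p-values use the add-one correction (1 + #{null >= obs}) /
(1 + n_perm), so the smallest achievable p is 1/(n_perm + 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .reference import GranularityMap, ReferenceTaxonomy

__all__ = [
    "AccuracyReport",
    "ColocResult",
    "SpDEGResult",
    "truth_adjacency",
    "accuracy_at_grouping",
    "assignment_accuracy",
    "type_correlation",
    "colocalization_test",
    "spdeg_test",
    "DEFAULT_HEIGHTS",
]

DEFAULT_HEIGHTS = np.round(np.arange(0.0, 0.8001, 0.05), 3)

_OFFSETS_26 = np.array(
    [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
)


def truth_adjacency(labels: np.ndarray) -> np.ndarray:
    """Boolean (max_id+1, max_id+1) touching matrix over 26-connectivity."""
    n = int(labels.max())
    adj = np.zeros((n + 1, n + 1), dtype=bool)
    padded = np.pad(labels, 1, constant_values=0)
    sh = padded.shape
    for o in _OFFSETS_26:
        nb = padded[
            1 + o[0] : sh[0] - 1 + o[0],
            1 + o[1] : sh[1] - 1 + o[1],
            1 + o[2] : sh[2] - 1 + o[2],
        ]
        mask = (labels > 0) & (nb > 0) & (labels != nb)
        if mask.any():
            adj[labels[mask], nb[mask]] = True
    return adj | adj.T


@dataclass
class AccuracyReport:
    """Mean taxonomy-aware assignment accuracy across granularity cuts."""

    heights: np.ndarray
    n_groups: np.ndarray
    mean_accuracy: np.ndarray
    per_cell: dict = field(default_factory=dict)  # height -> (cell ids, acc)
    n_empty_cells: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "height": self.heights,
                "n_groups": self.n_groups,
                "mean_accuracy": self.mean_accuracy,
            }
        )


def accuracy_at_grouping(
    spot_assignments: np.ndarray,
    truth,
    grouping: GranularityMap,
    *,
    adjacency: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray, int]:
    """Per-cell and mean accuracy at one granularity cut.

    A spot assigned to predicted cell ``c`` is correct when its true cell is
    ``c``, or a touching neighbour of ``c`` whose true type maps to the same
    group as ``c``'s. Cells with zero assigned spots are excluded.
    Returns (mean, cell ids with spots, per-cell accuracies).
    """
    assign = np.asarray(spot_assignments)
    true_cell = truth.spots.true_cell
    if true_cell is None or len(true_cell) != len(assign):
        raise ValueError("truth and prediction must share the spot table")
    adj = truth_adjacency(truth.labels) if adjacency is None else adjacency
    group = grouping.group_of
    # group of each true cell; -1 for background
    cell_group = np.full(len(truth.true_types), -1, dtype=np.int64)
    live = truth.true_types >= 0
    cell_group[live] = group[truth.true_types[live]]

    assigned = assign > 0
    a, t = assign[assigned], true_cell[assigned]
    valid_pair = (a < adj.shape[0]) & (t > 0)
    correct = np.zeros(len(a), dtype=bool)
    correct[a == t] = True
    vp = valid_pair & (a != t)
    correct[vp] = adj[a[vp], t[vp]] & (cell_group[a[vp]] == cell_group[t[vp]])

    ids = np.unique(a)
    n_spots = np.bincount(a, minlength=ids.max() + 1)
    n_correct = np.bincount(a, weights=correct.astype(float), minlength=ids.max() + 1)
    per_cell = n_correct[ids] / n_spots[ids]
    return float(per_cell.mean()), ids, per_cell


def assignment_accuracy(
    results_or_assignments,
    truth,
    taxonomy: ReferenceTaxonomy | None = None,
    heights: np.ndarray = DEFAULT_HEIGHTS,
) -> AccuracyReport:
    """Accuracy swept over granularity heights (default 0→0.8, step 0.05)."""
    if hasattr(results_or_assignments, "spot_assignments"):
        assign = results_or_assignments.spot_assignments
    else:
        assign = np.asarray(results_or_assignments)
    taxonomy = taxonomy or truth.taxonomy
    adj = truth_adjacency(truth.labels)
    means, n_groups, per_cell = [], [], {}
    # predicted cells that own pixels but received no spots
    n_empty = 0
    if hasattr(results_or_assignments, "labels"):
        pred_cells = np.unique(results_or_assignments.labels)
        pred_cells = pred_cells[pred_cells > 0]
        with_spots = np.unique(assign[assign > 0])
        n_empty = int(len(np.setdiff1d(pred_cells, with_spots)))
    for h in heights:
        gmap = taxonomy.grouping(float(h))
        mean, ids, acc = accuracy_at_grouping(assign, truth, gmap, adjacency=adj)
        means.append(mean)
        n_groups.append(gmap.n_groups)
        per_cell[float(h)] = (ids, acc)
    return AccuracyReport(
        heights=np.asarray(heights, float),
        n_groups=np.asarray(n_groups),
        mean_accuracy=np.asarray(means),
        per_cell=per_cell,
        n_empty_cells=n_empty,
    )


def type_correlation(
    E_c: np.ndarray,
    T_c: np.ndarray,
    reference: ReferenceTaxonomy,
    *,
    min_mean_counts: float = 5.0,
) -> pd.Series:
    """Per-type Pearson correlation of mean expression between the segmented
    cells and the reference, over genes with mean >= ``min_mean_counts`` in at
    least one type of the segmented data; values are centred and scaled across
    types within each modality first."""
    E_c = np.asarray(E_c, float)
    T_c = np.asarray(T_c)
    types = np.intersect1d(np.unique(T_c), np.arange(reference.n_types))
    if types.size < 1:
        raise ValueError("no shared types")
    meas = np.stack([E_c[T_c == t].mean(axis=0) for t in types])
    ref = reference.mu[types]
    keep = (meas >= min_mean_counts).any(axis=0)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 genes pass the expression filter")
    meas, ref = meas[:, keep], ref[:, keep]

    def _z(M):
        mu = M.mean(axis=0)
        sd = M.std(axis=0)
        sd[sd == 0] = 1.0
        return (M - mu) / sd

    meas, ref = _z(meas), _z(ref)
    r = np.empty(len(types))
    for i in range(len(types)):
        a, b = meas[i], ref[i]
        denom = a.std() * b.std()
        r[i] = 0.0 if denom == 0 else float(np.mean((a - a.mean()) * (b - b.mean())) / denom)
    return pd.Series(r, index=[reference.type_names[t] for t in types], name="pearson_r")


@dataclass
class ColocResult:
    """Observed neighbour-composition matrix and its permutation test."""

    types: np.ndarray  # type ids present, rows/cols of the matrices
    observed: np.ndarray  # (k', k') mean neighbour fractions
    p: np.ndarray
    q: np.ndarray
    n_perm: int
    k_neighbors: int

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.q < alpha


def _neighbor_fraction_matrix(
    nbr_types: np.ndarray, cell_types: np.ndarray, k_prime: int
) -> np.ndarray:
    """Mean over cells of each type of the per-cell neighbour-type fractions."""
    n, kn = nbr_types.shape
    counts = np.zeros((n, k_prime))
    rows = np.repeat(np.arange(n), kn)
    np.add.at(counts, (rows, nbr_types.ravel()), 1.0)
    frac = counts / kn
    out = np.zeros((k_prime, k_prime))
    for t in range(k_prime):
        sel = cell_types == t
        if sel.any():
            out[t] = frac[sel].mean(axis=0)
    return out


def colocalization_test(
    centroids: np.ndarray,
    T_c: np.ndarray,
    *,
    k_neighbors: int = 20,
    n_perm: int = 1000,
    seed: int = 0,
) -> ColocResult:
    """Permutation test for (sub)type colocalization.

    The observed statistic for (a, b) is the mean, over cells of type a, of
    the fraction of their ``k_neighbors`` nearest neighbours of type b. The
    null permutes cell-type labels ``n_perm`` times; p is the add-one fraction
    of null values >= observed; q is Benjamini-Hochberg across all pairs.
    """
    centroids = np.asarray(centroids, float)
    T_c = np.asarray(T_c)
    n = len(T_c)
    if n <= k_neighbors:
        raise ValueError("need more cells than k_neighbors")
    types_present, T_idx = np.unique(T_c, return_inverse=True)
    kp = len(types_present)
    nbr = cKDTree(centroids).query(centroids, k=k_neighbors + 1)[1][:, 1:]
    rng = np.random.default_rng(seed)

    observed = _neighbor_fraction_matrix(T_idx[nbr], T_idx, kp)
    exceed = np.zeros((kp, kp))
    for _ in range(n_perm):
        perm = rng.permutation(T_idx)
        null = _neighbor_fraction_matrix(perm[nbr], perm, kp)
        exceed += null >= observed
    p = (1.0 + exceed) / (1.0 + n_perm)
    q = multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
    return ColocResult(
        types=types_present, observed=observed, p=p, q=q,
        n_perm=n_perm, k_neighbors=k_neighbors,
    )


@dataclass
class SpDEGResult:
    """Spatial differential expression: per (type, gene) statistics."""

    table: pd.DataFrame  # columns: type, gene, stat, p, q
    tested_types: np.ndarray
    skipped_types: np.ndarray
    n_perm: int
    local_expression: dict = field(default_factory=dict)  # type -> (n_t, g) matrix

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < alpha]


def spdeg_test(
    centroids: np.ndarray,
    E_c: np.ndarray,
    T_c: np.ndarray,
    *,
    genes_tested: np.ndarray | None = None,
    min_cells: int = 40,
    k_local: int = 9,
    n_perm: int = 100,
    seed: int = 0,
    per_type_correction: bool = False,
) -> SpDEGResult:
    """Permutation test for spatially differentially expressed genes.

    Within each type with more than ``min_cells`` cells, the local expression
    of a gene at a cell is the mean over the cell and its ``k_local`` nearest
    same-type neighbours; the statistic is the variance of local expression
    across cells. The null permutes the gene's values among that type's
    cells. BH correction is applied jointly across all (type, gene) pairs
    unless ``per_type_correction``.
    """
    centroids = np.asarray(centroids, float)
    E_c = np.asarray(E_c, float)
    T_c = np.asarray(T_c)
    genes = (
        np.arange(E_c.shape[1]) if genes_tested is None else np.asarray(genes_tested)
    )
    rng = np.random.default_rng(seed)
    rows = []
    tested, skipped = [], []
    local_expr: dict = {}
    for t in np.unique(T_c):
        idx = np.flatnonzero(T_c == t)
        if len(idx) <= min_cells:
            skipped.append(t)
            continue
        tested.append(t)
        n_t = len(idx)
        kq = min(k_local + 1, n_t)
        nbr = cKDTree(centroids[idx]).query(centroids[idx], k=kq)[1]
        perms = np.stack([rng.permutation(n_t) for _ in range(n_perm)])
        loc_mat = np.empty((n_t, len(genes)))
        for gi, g in enumerate(genes):
            vals = E_c[idx, g]
            local = vals[nbr].mean(axis=1)
            loc_mat[:, gi] = local
            obs = local.var()
            null = vals[perms][:, nbr].mean(axis=2).var(axis=1)
            p = (1.0 + (null >= obs).sum()) / (1.0 + n_perm)
            rows.append({"type": t, "gene": int(g), "stat": float(obs), "p": float(p)})
        local_expr[int(t)] = loc_mat
    if not rows:
        raise ValueError(f"no type exceeds {min_cells} cells")
    table = pd.DataFrame(rows)
    if per_type_correction:
        table["q"] = np.nan
        for t in table["type"].unique():
            sel = table["type"] == t
            table.loc[sel, "q"] = multipletests(table.loc[sel, "p"], method="fdr_bh")[1]
    else:
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    return SpDEGResult(
        table=table,
        tested_types=np.asarray(tested),
        skipped_types=np.asarray(skipped),
        n_perm=n_perm,
        local_expression=local_expr,
    )
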