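"""Joint segmentation and typing: the EM engine and the watershed baseline.

The model alternates between (M) training a pixel-level type classifier on
the current assignment of pixels to typed cells and (E) stochastically
reassigning border pixels according to classifier probabilities rescaled by
distance to candidate nuclei, annealed toward the argmax over iterations.

`JointSegmentationModel` is built from a spot table, nuclei seeds and a
reference taxonomy; `fit()` runs the full EM schedule and returns a
`SegmentationResults`; `fit_watershed()` runs the density-watershed baseline
on the same grid for comparison.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .classify import (
    CellClassifier,
    PixelClassifier,
    TrainConfig,
    classify_cells,
    pixel_type_probabilities,
    train_cell_classifier,
    train_pixel_classifier,
)
from .density import PixelGrid, build_grid, knn_density
from .io import NucleiSeeds, SpotTable
from .reference import ReferenceTaxonomy, harmonize_expression

__all__ = [
    "ReassignmentParams",
    "SegmentationState",
    "JointSegmentationModel",
    "SegmentationResults",
    "watershed_initialize",
    "watershed_baseline",
    "border_pixels",
    "rescale_pixel_probabilities",
    "anneal_and_sample",
    "counts_from_segmentation",
]

_OFFSETS_26 = np.array(
    [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
)


@dataclass
class ReassignmentParams:
    """Schedule and constants of the EM reassignment loop.

    ``d`` is both the watershed-initialization radius and the automatic
    assignment distance (μm). Empirical defaults: probability floor 0.05,
    6 training rounds × 10 reassignment iterations; simulations use 0.01 and
    5 × 5.
    """

    d: float = 2.0
    prob_floor: float = 0.05
    anneal_rate: float = 0.05
    n_train_rounds: int = 6
    n_reassign_iters: int = 10
    pixel_sample_frac: float = 0.10
    decay: str = "rational"  # or "exponential"
    retype_each_iteration: bool = False
    flip_tol_frac: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d <= 0 or not (0 < self.prob_floor < 1):
            raise ValueError("d must be positive and prob_floor in (0, 1)")
        if self.decay not in ("rational", "exponential"):
            raise ValueError("decay must be 'rational' or 'exponential'")

    @classmethod
    def for_simulation(cls, seed: int = 0, **kw) -> "ReassignmentParams":
        kw.setdefault("prob_floor", 0.01)
        kw.setdefault("n_train_rounds", 5)
        kw.setdefault("n_reassign_iters", 5)
        return cls(seed=seed, **kw)


@dataclass
class SegmentationState:
    """Mutable segmentation state: labels, types, counts, iteration."""

    labels: np.ndarray  # (nx, ny, nz) int32, aligned to PixelGrid
    nucleus_mask: np.ndarray  # (nx, ny, nz) bool, frozen pixels
    nucleus_centroids: np.ndarray  # (max_id + 1, 3) μm
    T_c: np.ndarray  # (max_id + 1,) int; -1 where undefined/background
    E_c: np.ndarray | None = None  # (max_id + 1, m) current counts
    iteration: int = 0

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


# --------------------------------------------------------------------------- #
# initialization                                                               #
# --------------------------------------------------------------------------- #


def _nuclei_on_grid(grid: PixelGrid, nuclei: NucleiSeeds) -> np.ndarray:
    """Resample the nuclei label volume onto the pixel grid (nearest voxel at
    each pixel centre)."""
    centers = grid.pixel_centers()
    idx = np.floor((centers - nuclei.origin) / nuclei.voxel_size).astype(np.int64)
    sh = np.asarray(nuclei.labels.shape)
    inside = np.all((idx >= 0) & (idx < sh), axis=1)
    out = np.zeros(grid.n_pixels, dtype=np.int32)
    ii = idx[inside]
    out[inside] = nuclei.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out.reshape(grid.shape)


def watershed_initialize(
    grid: PixelGrid, nuclei: NucleiSeeds, d: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Initial map: watershed on the Euclidean distance transform from the
    nuclei, with assignment capped at ``d`` μm from the nucleus surface.

    Returns (labels volume, nucleus mask on the grid).
    """
    seeds = _nuclei_on_grid(grid, nuclei)
    if seeds.max() == 0:
        raise ValueError("no nuclei fall inside the grid")
    missing = np.setdiff1d(nuclei.ids(), np.unique(seeds))
    if missing.size:
        warnings.warn(f"{missing.size} nuclei have no grid pixel and were dropped")
    edt = ndimage.distance_transform_edt(seeds == 0, sampling=grid.pixel_size)
    mask = edt <= d
    labels = watershed(edt, markers=seeds, mask=mask).astype(np.int32)
    return labels, seeds > 0


def watershed_baseline(
    grid: PixelGrid,
    E_p: np.ndarray,
    nuclei: NucleiSeeds,
    *,
    compactness: float = 10.0,
    mask_threshold: float = 1.0,
) -> np.ndarray:
    """Density-watershed baseline segmentation.

    Sums densities over genes, log2-transforms, masks transformed values
    below ``mask_threshold``, and runs compactness-weighted watershed on the
    negated surface from the nuclei seeds with a one-pixel separating line.
    Nucleus pixels are always kept in the mask so every seed survives.
    """
    total = E_p.sum(axis=1).reshape(grid.shape)
    logd = np.log2(np.maximum(total, 1e-30))
    seeds = _nuclei_on_grid(grid, nuclei)
    mask = logd >= mask_threshold
    if not mask.any():
        raise ValueError("all pixels fall below the density mask threshold")
    mask |= seeds > 0
    labels = watershed(
        -logd, markers=seeds, mask=mask, compactness=compactness
    ).astype(np.int32)
    # skimage's compact watershed does not emit the separating line itself;
    # strip a one-pixel line where a cell faces a lower-labelled cell
    line = np.zeros(labels.shape, dtype=bool)
    padded = np.pad(labels, 1, constant_values=0)
    for o in np.array([(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]):
        nb = _shift(padded, o)
        line |= (labels > 0) & (nb > 0) & (nb < labels)
    labels[line] = 0
    return labels


# --------------------------------------------------------------------------- #
# border pixels                                                               #
# --------------------------------------------------------------------------- #


def _shift(padded: np.ndarray, o: np.ndarray) -> np.ndarray:
    sh = padded.shape
    return padded[
        1 + o[0] : sh[0] - 1 + o[0],
        1 + o[1] : sh[1] - 1 + o[1],
        1 + o[2] : sh[2] - 1 + o[2],
    ]


def _max_same_label_run(nb: np.ndarray) -> np.ndarray:
    """Per row, the largest multiplicity of any positive label (vectorized)."""
    S = np.sort(nb, axis=1)
    best = (S[:, 0] > 0).astype(np.int64)
    cur = np.ones(len(S), dtype=np.int64)
    for j in range(1, S.shape[1]):
        cont = (S[:, j] == S[:, j - 1]) & (S[:, j] > 0)
        cur = np.where(cont, cur + 1, 1)
        best = np.maximum(best, np.where(S[:, j] > 0, cur, 0))
    return best


def border_pixels(
    labels: np.ndarray,
    T_c: np.ndarray,
    nucleus_mask: np.ndarray,
    *,
    min_diff: int = 5,
    min_same: int = 2,
) -> np.ndarray:
    """Indices (n, 3) of pixels eligible for reassignment.

    A labelled pixel is a border pixel iff, over its 26-neighbourhood, at
    least ``min_diff`` neighbours belong to a different cell (background and
    out-of-volume count as different), at least ``min_same`` belong to its own
    cell, and at least one differing neighbour is background or a cell of a
    *different type* (interfaces between same-type cells are frozen). A
    background pixel is eligible for accretion when some single adjacent cell
    owns >= ``min_diff`` of its neighbours and >= ``min_same`` neighbours are
    background. Nucleus pixels are never eligible.
    """
    padded = np.pad(labels, 1, constant_values=0)
    tmap = np.concatenate([T_c, [-1]])  # guard; labels always < len(T_c)
    same = np.zeros(labels.shape, dtype=np.int16)
    n_bg = np.zeros(labels.shape, dtype=np.int16)
    has_bg = np.zeros(labels.shape, dtype=bool)
    has_difftype = np.zeros(labels.shape, dtype=bool)
    own_type = tmap[labels]
    for o in _OFFSETS_26:
        nb = _shift(padded, o)
        same += (nb == labels) & (labels > 0)
        bg = nb == 0
        n_bg += bg
        has_bg |= bg
        has_difftype |= (nb > 0) & (tmap[nb] != own_type)

    labelled = labels > 0
    diff = 26 - same
    border = (
        labelled
        & (diff >= min_diff)
        & (same >= min_same)
        & (has_bg | has_difftype)
        & ~nucleus_mask
    )

    # background accretion candidates
    bg_cand = (~labelled) & (n_bg >= min_same) & ((26 - n_bg) >= min_diff)
    if bg_cand.any():
        idx = np.argwhere(bg_cand)
        nb = np.stack(
            [_shift(padded, o)[idx[:, 0], idx[:, 1], idx[:, 2]] for o in _OFFSETS_26],
            axis=1,
        )
        ok = _max_same_label_run(nb) >= min_diff
        keep = np.zeros(labels.shape, dtype=bool)
        keep[idx[ok, 0], idx[ok, 1], idx[ok, 2]] = True
        bg_cand = keep
    return np.argwhere(border | bg_cand)


# --------------------------------------------------------------------------- #
# probability rescaling, annealing, sampling                                  #
# --------------------------------------------------------------------------- #


def rescale_pixel_probabilities(
    q: np.ndarray,
    r_to_nearest: np.ndarray,
    d: float,
    prob_floor: float,
    *,
    decay: str = "rational",
    cap: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance-rescale classifier probabilities and re-normalize.

    ``q`` is (n, k); ``r_to_nearest`` is (n, k) with the distance (μm) from
    each pixel to the nearest nucleus of each type among *adjacent* cells, and
    ``inf`` for types not present among neighbours. Within ``d`` of a nucleus
    the type dominates outright (value ``cap``); beyond, the probability
    decays as q·(5d)/(2(r−d)) (halved at r = 6d), capped at ``cap``; types not
    in the neighbourhood get 0; entries below ``prob_floor`` after
    renormalization are zeroed. Rows whose entries are all zero are flagged
    background.

    Returns (rescaled rows summing to 1 or all-zero, background flags).
    """
    q = np.asarray(q, np.float64)
    r = np.asarray(r_to_nearest, np.float64)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    neighbor = np.isfinite(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        if decay == "rational":
            factor = (5.0 * d) / (2.0 * (r - d))
            factor[r <= d] = np.inf
            decayed = np.minimum(q * factor, cap)
        elif decay == "exponential":
            decayed = np.minimum(q * 0.5 ** ((r - d) / (5.0 * d)), cap)
        else:
            raise ValueError("decay must be 'rational' or 'exponential'")
    qp = np.where(r < d, cap, decayed)
    qp = np.where(neighbor, qp, 0.0)
    qp = np.nan_to_num(qp, nan=0.0, posinf=cap)

    def _floor_and_norm(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tot = x.sum(axis=1, keepdims=True)
        bg = tot.ravel() <= 0
        safe = np.where(tot > 0, tot, 1.0)
        x = x / safe
        x[x < prob_floor] = 0.0
        return x, bg

    qp, bg1 = _floor_and_norm(qp)
    qp, bg2 = _floor_and_norm(qp)
    background = bg1 | bg2
    qp[background] = 0.0
    return qp, background


def anneal_and_sample(
    q: np.ndarray,
    iteration: int,
    rng: np.random.Generator,
    *,
    anneal_rate: float = 0.05,
) -> np.ndarray:
    """Boost each row's maximum by (1 + iteration·anneal_rate), renormalize,
    and draw one type per row from the resulting multinomial. Rows summing to
    zero return -1 (background)."""
    q = np.asarray(q, np.float64).copy()
    n, k = q.shape
    tot = q.sum(axis=1)
    valid = tot > 0
    out = np.full(n, -1, dtype=np.int64)
    if not valid.any():
        return out
    qv = q[valid]
    arg = qv.argmax(axis=1)
    qv[np.arange(len(qv)), arg] *= 1.0 + iteration * anneal_rate
    qv /= qv.sum(axis=1, keepdims=True)
    cdf = np.cumsum(qv, axis=1)
    u = rng.random(len(qv))
    out[valid] = np.minimum((u[:, None] > cdf).sum(axis=1), k - 1)
    return out


# --------------------------------------------------------------------------- #
# counts                                                                      #
# --------------------------------------------------------------------------- #


def counts_from_segmentation(
    labels: np.ndarray, grid: PixelGrid, spots: SpotTable
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each spot to the cell owning its pixel.

    Returns (E_c indexed by cell id, shape (max_id + 1, m); per-spot cell id
    with 0 for background). Spots outside the grid count as background with a
    warning.
    """
    idx = grid.point_to_index(spots.xyz)
    inside = grid.inside(idx)
    if not inside.all():
        warnings.warn(f"{int((~inside).sum())} spots outside the grid -> background")
    assign = np.zeros(len(spots), dtype=np.int64)
    ii = idx[inside]
    assign[inside] = labels[ii[:, 0], ii[:, 1], ii[:, 2]]
    m = spots.n_genes
    E_c = np.zeros((int(labels.max()) + 1, m), dtype=np.int64)
    np.add.at(E_c, (assign, spots.gene), 1)
    return E_c, assign


# --------------------------------------------------------------------------- #
# the model                                                                   #
# --------------------------------------------------------------------------- #


class JointSegmentationModel:
    """Joint cell segmentation and typing model for a spot table + nuclei.

    Parameters
    ----------
    spots, nuclei, reference
        The observed transcript table, the nuclei seed volume, and the
        reference taxonomy used for typing.
    pixel_size
        Grid edge in μm (2 for empirical data, 1 in simulations).
    marker_genes
        Indices of genes fed to the classifiers; defaults to the spot panel's
        marker mask. Counting always uses the full panel.
    params
        :class:`ReassignmentParams` (EM schedule); simulation defaults via
        ``ReassignmentParams.for_simulation()``.
    """

    def __init__(
        self,
        spots: SpotTable,
        nuclei: NucleiSeeds,
        reference: ReferenceTaxonomy,
        *,
        pixel_size: float = 2.0,
        knn_k: int = 5,
        marker_genes: np.ndarray | None = None,
        params: ReassignmentParams | None = None,
        cell_train_cfg: TrainConfig | None = None,
        pixel_cold_cfg: TrainConfig | None = None,
        pixel_warm_cfg: TrainConfig | None = None,
    ) -> None:
        self.spots = spots
        self.nuclei = nuclei
        self.reference = reference
        self.params = params or ReassignmentParams()
        self.cell_train_cfg = cell_train_cfg
        self.pixel_cold_cfg = pixel_cold_cfg
        self.pixel_warm_cfg = pixel_warm_cfg
        self.knn_k = knn_k
        self.marker_genes = (
            spots.panel.marker_indices if marker_genes is None else np.asarray(marker_genes)
        )
        if self.marker_genes.size == 0:
            raise ValueError("marker gene subset must be non-empty")
        self.grid = build_grid(spots, nuclei, pixel_size)
        self.E_p = knn_density(spots, self.grid, K=knn_k)
        self._centers = self.grid.pixel_centers()
        # pixel features: log1p density, per-gene z-score frozen now
        feats = np.log1p(self.E_p[:, self.marker_genes])
        self._feat_mean = feats.mean(axis=0)
        self._feat_sd = feats.std(axis=0)
        self._feat_sd[self._feat_sd == 0] = 1.0
        self._features = (feats - self._feat_mean) / self._feat_sd
        self._cell_clf: CellClassifier | None = None

    # -- classifiers --------------------------------------------------------
    @property
    def cell_classifier(self) -> CellClassifier:
        if self._cell_clf is None:
            E_ref = self.reference.E_ref[:, self.marker_genes]
            self._cell_clf = train_cell_classifier(
                harmonize_expression(E_ref),
                self.reference.T_ref,
                self.cell_train_cfg,
                n_types=self.reference.n_types,
            )
        return self._cell_clf

    def _classify_current_cells(self, labels: np.ndarray) -> np.ndarray:
        E_c, _ = counts_from_segmentation(labels, self.grid, self.spots)
        T_c = np.full(E_c.shape[0], -1, dtype=np.int64)
        ids = np.unique(labels)
        ids = ids[ids > 0]
        if ids.size >= 2:
            E = harmonize_expression(E_c[ids][:, self.marker_genes].astype(float))
            _, types = classify_cells(self.cell_classifier, E)
            T_c[ids] = types
        elif ids.size == 1:
            T_c[ids] = 0
        return T_c

    # -- fitting ------------------------------------------------------------
    def fit(self, seed: int | None = None, callback=None) -> "SegmentationResults":
        """Run the full EM schedule and return the fitted segmentation.

        ``callback(state, iteration)``, when given, is invoked after every
        reassignment iteration (diagnostics / invariant checking hook).
        """
        p = self.params
        rng = np.random.default_rng(p.seed if seed is None else seed)
        labels, nucleus_mask = watershed_initialize(self.grid, self.nuclei, d=p.d)
        T_c = self._classify_current_cells(labels)
        state = SegmentationState(
            labels=labels,
            nucleus_mask=nucleus_mask,
            nucleus_centroids=self.nuclei.centroids,
            T_c=T_c,
        )
        diagnostics: dict = {"flips": [], "border_counts": [], "mean_max_prob": []}
        initial_ids = set(map(int, state.cell_ids))

        types_present = np.unique(T_c[labels[labels > 0]])
        if types_present.size < 2:
            # single-type input: every interface is frozen, EM is a no-op
            diagnostics["note"] = "fewer than two cell types; EM skipped"
            return self._finalize(state, diagnostics, method="em", seed=seed)

        pix_clf: PixelClassifier | None = None
        flat_labels = state.labels.reshape(-1)
        global_iter = 0
        k = self.reference.n_types
        for rnd in range(p.n_train_rounds):
            assigned = np.flatnonzero(flat_labels > 0)
            n_sample = max(2, int(round(p.pixel_sample_frac * assigned.size)))
            sample = rng.choice(assigned, size=min(n_sample, assigned.size), replace=False)
            y = state.T_c[flat_labels[sample]]
            if len(np.unique(y)) < 2:
                diagnostics.setdefault("note", "training sample degenerate; stopped")
                break
            cold = self.pixel_cold_cfg
            warm = self.pixel_warm_cfg
            pix_clf = train_pixel_classifier(
                self._features[sample],
                y,
                (cold if pix_clf is None else warm),
                warm_start=pix_clf,
                n_types=k,
            )
            probs = pixel_type_probabilities(pix_clf, self._features[sample])
            diagnostics["mean_max_prob"].append(float(probs.max(axis=1).mean()))

            for _ in range(p.n_reassign_iters):
                n_flips, n_border = self._reassign_once(
                    state, pix_clf, global_iter, rng
                )
                diagnostics["flips"].append(int(n_flips))
                diagnostics["border_counts"].append(int(n_border))
                global_iter += 1
                state.iteration = global_iter
                if p.retype_each_iteration:
                    state.T_c = self._classify_current_cells(state.labels)
                if callback is not None:
                    callback(state, global_iter)
                if n_border == 0 or n_flips < p.flip_tol_frac * max(n_border, 1):
                    break
            flat_labels = state.labels.reshape(-1)

        final_ids = set(map(int, state.cell_ids))
        if not final_ids <= initial_ids:
            raise AssertionError("EM created cell ids not present at initialization")
        diagnostics["n_iterations"] = global_iter
        return self._finalize(state, diagnostics, method="em", seed=seed)

    def _reassign_once(
        self,
        state: SegmentationState,
        pix_clf: PixelClassifier,
        iteration: int,
        rng: np.random.Generator,
    ) -> tuple[int, int]:
        p = self.params
        labels = state.labels
        bidx = border_pixels(labels, state.T_c, state.nucleus_mask)
        n_border = len(bidx)
        if n_border == 0:
            return 0, 0
        padded = np.pad(labels, 1, constant_values=0)
        nb = np.stack(
            [_shift(padded, o)[bidx[:, 0], bidx[:, 1], bidx[:, 2]] for o in _OFFSETS_26],
            axis=1,
        )  # (B, 26) neighbour labels
        own = labels[bidx[:, 0], bidx[:, 1], bidx[:, 2]]
        k = self.reference.n_types

        flat = self.grid.ravel_index(bidx)
        centers = self._centers[flat]
        cents = state.nucleus_centroids[nb]  # (B, 26, 3); nan for label 0
        with np.errstate(invalid="ignore"):
            dist = np.linalg.norm(cents - centers[:, None, :], axis=2)
        dist = np.where(nb > 0, dist, np.inf)
        dist = np.nan_to_num(dist, nan=np.inf)

        nb_types = np.where(nb > 0, state.T_c[nb], -1)
        r = np.full((n_border, k), np.inf)
        rows = np.repeat(np.arange(n_border), nb.shape[1])
        tt = nb_types.ravel()
        ok = tt >= 0
        np.minimum.at(r, (rows[ok], tt[ok]), dist.ravel()[ok])

        q = pixel_type_probabilities(pix_clf, self._features[flat])
        q2, bg = rescale_pixel_probabilities(
            q, r, p.d, p.prob_floor, decay=p.decay
        )
        drawn = anneal_and_sample(q2, iteration, rng, anneal_rate=p.anneal_rate)

        # target cell: own cell when the drawn type matches it (frozen
        # same-type interfaces); otherwise the nearest adjacent cell of the
        # drawn type; background when flagged
        target = np.zeros(n_border, dtype=np.int64)
        live = drawn >= 0
        if live.any():
            match = nb_types[live] == drawn[live][:, None]
            dmask = np.where(match, dist[live], np.inf)
            j = dmask.argmin(axis=1)
            target[live] = nb[live][np.arange(int(live.sum())), j]
            own_live = own[live]
            own_type = np.where(own_live > 0, state.T_c[own_live], -2)
            stay = own_type == drawn[live]
            tl = target[live]
            tl[stay] = own_live[stay]
            target[live] = tl
        target[bg | (drawn < 0)] = 0

        flips = target != own
        if flips.any():
            f = bidx[flips]
            labels[f[:, 0], f[:, 1], f[:, 2]] = target[flips].astype(np.int32)
        return int(flips.sum()), n_border

    def fit_watershed(
        self, *, compactness: float = 10.0, mask_threshold: float = 1.0
    ) -> "SegmentationResults":
        """Density-watershed baseline on the same grid (no EM)."""
        labels = watershed_baseline(
            self.grid, self.E_p, self.nuclei,
            compactness=compactness, mask_threshold=mask_threshold,
        )
        seeds = _nuclei_on_grid(self.grid, self.nuclei)
        T_c = self._classify_current_cells(labels)
        state = SegmentationState(
            labels=labels,
            nucleus_mask=seeds > 0,
            nucleus_centroids=self.nuclei.centroids,
            T_c=T_c,
        )
        return self._finalize(state, {"note": "watershed baseline"}, method="watershed")

    def _finalize(
        self, state: SegmentationState, diagnostics: dict, *, method: str,
        seed: int | None = None,
    ) -> "SegmentationResults":
        E_c, assign = counts_from_segmentation(state.labels, self.grid, self.spots)
        state.E_c = E_c
        return SegmentationResults(
            model=self, state=state, diagnostics=diagnostics,
            spot_assignments=assign, method=method, seed=seed,
        )


class SegmentationResults:
    """Fitted segmentation: labels, per-cell counts and types, diagnostics."""

    def __init__(self, model, state, diagnostics, spot_assignments, method, seed=None):
        self.model = model
        self.state = state
        self.diagnostics = diagnostics
        self.spot_assignments = spot_assignments
        self.method = method
        self.seed = seed

    # -- accessors ----------------------------------------------------------
    @property
    def grid(self) -> PixelGrid:
        return self.model.grid

    @property
    def spots(self) -> SpotTable:
        return self.model.spots

    @property
    def labels(self) -> np.ndarray:
        return self.state.labels

    @property
    def cell_ids(self) -> np.ndarray:
        return self.state.cell_ids

    @property
    def cell_counts(self) -> np.ndarray:
        """(n_cells, m) spot counts over the full panel, rows = cell_ids."""
        return self.state.E_c[self.cell_ids]

    @property
    def cell_types(self) -> np.ndarray:
        return self.state.T_c[self.cell_ids]

    @property
    def type_names(self) -> list[str]:
        return self.model.reference.type_names

    @property
    def n_background_spots(self) -> int:
        return int((self.spot_assignments == 0).sum())

    def cell_centroids(self) -> np.ndarray:
        """(n_cells, 3) physical centroids of the segmented cells (μm)."""
        ids = self.cell_ids
        coms = ndimage.center_of_mass(
            np.ones_like(self.labels, dtype=np.uint8), self.labels, index=ids
        )
        return np.asarray(coms) * self.grid.pixel_size + self.grid.origin + (
            self.grid.pixel_size / 2.0
        )

    def manifest(self) -> dict:
        return {
            "method": self.method,
            "seed": self.seed,
            "pixel_size": self.grid.pixel_size,
            "knn_k": self.model.knn_k,
            "marker_genes": self.model.marker_genes.tolist(),
            "params": asdict(self.model.params),
            "n_cells": int(len(self.cell_ids)),
            "n_spots": int(len(self.spots)),
            "n_background_spots": self.n_background_spots,
            "diagnostics": {
                key: val for key, val in self.diagnostics.items()
            },
        }

    def summary(self) -> str:
        lines = [
            "Joint segmentation results",
            "=" * 40,
            f"method:            {self.method}",
            f"grid shape:        {self.grid.shape} @ {self.grid.pixel_size} um",
            f"cells:             {len(self.cell_ids)}",
            f"types present:     {len(np.unique(self.cell_types))}",
            f"spots assigned:    {len(self.spots) - self.n_background_spots}"
            f" / {len(self.spots)}",
        ]
        flips = self.diagnostics.get("flips")
        if flips:
            lines.append(f"EM iterations:     {len(flips)} (total flips {sum(flips)})")
        mmp = self.diagnostics.get("mean_max_prob")
        if mmp:
            lines.append(
                "mean max P(type):  " + " -> ".join(f"{v:.3f}" for v in mmp)
            )
        return "\n".join(lines)
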