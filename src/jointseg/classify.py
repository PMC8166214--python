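"""Cell-level and pixel-level type classifiers.

The cell classifier maps a harmonized per-cell expression vector to a
probability distribution over reference types; it is trained once on the
reference and then held fixed. The pixel classifier maps per-pixel marker
densities to the same type space and is retrained inside the segmentation
loop (warm-started from the previous round's parameters) on labels given by
the current assignment of pixels to typed cells.

Architectures
-------------
cell  : m → 3m → 3m → 3m → k   tanh + batch norm, L1 penalty 1e-4
pixel : m → 2m → 4m → 8m → k   tanh + batch norm, L2 penalty 1e-3
Both use Xavier init, Adam, batch size 64 and cross-entropy loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import MLP

__all__ = [
    "TrainConfig",
    "CellClassifier",
    "PixelClassifier",
    "train_cell_classifier",
    "classify_cells",
    "train_pixel_classifier",
    "pixel_type_probabilities",
]


@dataclass
class TrainConfig:
    """Learning-rate schedule and split for classifier training.

    ``phases`` is a list of (learning_rate, epochs) executed in order.
    """

    phases: list[tuple[float, int]]
    batch_size: int = 64
    val_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.phases or any(e <= 0 for _, e in self.phases):
            raise ValueError("every phase needs epochs > 0")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


CELL_TRAIN_DEFAULT = TrainConfig(phases=[(5e-3, 20), (5e-4, 20)], val_fraction=0.25)
PIXEL_COLD_DEFAULT = TrainConfig(phases=[(1e-3, 25), (1e-4, 25)], val_fraction=0.20)
PIXEL_WARM_DEFAULT = TrainConfig(phases=[(1e-4, 15)], val_fraction=0.20)


def _stratified_split(
    y: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split keeping at least one sample of each class in training."""
    train_idx, val_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(len(idx))]
        n_val = int(round(len(idx) * val_fraction))
        n_val = min(n_val, len(idx) - 1)
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


@dataclass
class CellClassifier:
    """Reference-trained cell-type classifier f_θ (fixed after training)."""

    net: MLP
    n_types: int
    trace: list = field(default_factory=list)

    def predict_proba(self, E_harmonized: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(E_harmonized)


@dataclass
class PixelClassifier:
    """Pixel-type classifier g_ϕ, retrained during the segmentation loop."""

    net: MLP
    n_types: int
    trace: list = field(default_factory=list)

    def predict_proba(self, rows: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(rows)


def _check_labels(y: np.ndarray, min_per_class: int = 2) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels must contain at least two types")
    if counts.min() < min_per_class:
        raise ValueError(
            f"every type needs >= {min_per_class} cells for a stratified split"
        )


def train_cell_classifier(
    E_ref_harmonized: np.ndarray,
    T_ref: np.ndarray,
    cfg: TrainConfig | None = None,
    *,
    n_types: int | None = None,
) -> CellClassifier:
    """Train f_θ on the harmonized reference with a 75/25 stratified split.

    Two phases of 20 epochs at learning rates 5e-3 then 5e-4 by default.
    Returns the classifier with per-epoch loss/accuracy traces attached.
    """
    cfg = cfg or CELL_TRAIN_DEFAULT
    X = np.asarray(E_ref_harmonized, np.float64)
    y = np.asarray(T_ref, np.int64)
    _check_labels(y)
    k = int(y.max()) + 1 if n_types is None else n_types
    m = X.shape[1]
    rng = np.random.default_rng(cfg.seed)
    tr, va = _stratified_split(y, cfg.val_fraction, rng)
    net = MLP(m, (3 * m, 3 * m, 3 * m), k, penalty="l1", lam=1e-4, seed=cfg.seed)
    trace: list = []
    for lr, epochs in cfg.phases:
        net.fit(
            X[tr], y[tr], epochs=epochs, lr=lr, batch_size=cfg.batch_size,
            rng=rng, X_val=X[va], y_val=y[va], trace=trace,
        )
    return CellClassifier(net=net, n_types=k, trace=trace)


def classify_cells(
    clf: CellClassifier, E_c_harmonized: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """P_c = f_θ(E_c) and T_c = argmax type (ties broken by lowest index)."""
    E = np.asarray(E_c_harmonized, np.float64)
    if E.shape[1] != clf.net.n_in:
        raise ValueError(
            f"gene panel mismatch: classifier expects {clf.net.n_in} genes, got {E.shape[1]}"
        )
    P_c = clf.predict_proba(E)
    T_c = P_c.argmax(axis=1)
    return P_c, T_c


def train_pixel_classifier(
    X_pixels: np.ndarray,
    y_types: np.ndarray,
    cfg: TrainConfig | None = None,
    *,
    warm_start: PixelClassifier | None = None,
    n_types: int | None = None,
) -> PixelClassifier:
    """Train (or warm-start retrain) g_ϕ on a sample of assigned pixels.

    Cold start: 25 epochs at 1e-3 then 25 at 1e-4, Xavier init.
    Warm start: 15 epochs at 1e-4 from the previous parameters.
    """
    X = np.asarray(X_pixels, np.float64)
    y = np.asarray(y_types, np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("pixel training labels contain fewer than two types")
    k = int(y.max()) + 1 if n_types is None else n_types
    m = X.shape[1]
    if warm_start is None:
        cfg = cfg or PIXEL_COLD_DEFAULT
        net = MLP(m, (2 * m, 4 * m, 8 * m), k, penalty="l2", lam=1e-3, seed=cfg.seed)
    else:
        cfg = cfg or PIXEL_WARM_DEFAULT
        net = warm_start.net.copy()
    rng = np.random.default_rng(cfg.seed)
    tr, va = _stratified_split(y, cfg.val_fraction, rng)
    trace: list = []
    for lr, epochs in cfg.phases:
        net.fit(
            X[tr], y[tr], epochs=epochs, lr=lr, batch_size=cfg.batch_size,
            rng=rng, X_val=X[va], y_val=y[va], trace=trace,
        )
    return PixelClassifier(net=net, n_types=k, trace=trace)


def pixel_type_probabilities(clf: PixelClassifier, rows: np.ndarray) -> np.ndarray:
    """Per-pixel type probabilities P_p for (already normalized) density rows."""
    rows = np.asarray(rows, np.float64)
    if not np.all(np.isfinite(rows)):
        raise ValueError("pixel feature rows contain non-finite values")
    return clf.predict_proba(rows)
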