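"""Input/output for spot tables, nuclei masks, references and segmentation results.

Conventions
-----------
* All physical coordinates are in micrometres (μm) in a right-handed frame.
* Label volumes are integer arrays indexed ``[ix, iy, iz]`` (x fastest-varying
  semantics are irrelevant; axes simply mirror the coordinate order x, y, z).
* Voxel/pixel indexing is 0-based with half-open bins ``[i*s, (i+1)*s)``;
  a point maps to a voxel by ``floor((coord - origin) / s)``.
* Label 0 is background everywhere.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

__all__ = [
    "GenePanel",
    "SpotTable",
    "NucleiSeeds",
    "read_spots",
    "consolidate_nuclei_masks",
    "write_outputs",
    "read_label_volume",
    "write_label_volume",
]


class FormatError(ValueError):
    """A file did not match the declared dialect/schema."""


class EmptyInputError(ValueError):
    """An input that must be non-empty was empty."""


@dataclass
class GenePanel:
    """Ordered gene panel with an optional marker subset.

    ``marker_mask[g]`` flags genes used by the classifiers for segmentation;
    the remaining (held-out) genes are still counted per cell and are the
    default pool for spatial differential-expression testing.
    """

    names: list[str]
    marker_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("gene panel names must be unique")
        if self.marker_mask is None:
            self.marker_mask = np.ones(len(self.names), dtype=bool)
        self.marker_mask = np.asarray(self.marker_mask, dtype=bool)
        if self.marker_mask.shape != (len(self.names),):
            raise ValueError("marker_mask length must match panel size")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def marker_indices(self) -> np.ndarray:
        return np.flatnonzero(self.marker_mask)

    def index_of(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class SpotTable:
    """Decoded transcript spots: coordinates (μm) plus gene index.

    ``true_cell`` is filled only by the tissue simulator (ground truth).
    """

    xyz: np.ndarray  # (n, 3) float64, μm
    gene: np.ndarray  # (n,) int
    panel: GenePanel
    true_cell: np.ndarray | None = None  # (n,) int, 0 = background

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        self.gene = np.asarray(self.gene, dtype=np.int64).ravel()
        if self.xyz.shape[0] != self.gene.shape[0]:
            raise ValueError("xyz and gene must have equal length")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("spot coordinates must be finite")
        m = len(self.panel)
        if self.gene.size and (self.gene.min() < 0 or self.gene.max() >= m):
            raise ValueError("gene indices must lie in [0, panel size)")
        if self.true_cell is not None:
            self.true_cell = np.asarray(self.true_cell, dtype=np.int64).ravel()
            if self.true_cell.shape != self.gene.shape:
                raise ValueError("true_cell length mismatch")

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.panel)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "x": self.xyz[:, 0],
                "y": self.xyz[:, 1],
                "z": self.xyz[:, 2],
                "gene": [self.panel.names[g] for g in self.gene],
            }
        )
        if self.true_cell is not None:
            df["true_cell"] = self.true_cell
        return df


@dataclass
class NucleiSeeds:
    """Labelled 3D nuclei volume on the same physical frame as the spots."""

    labels: np.ndarray  # (nx, ny, nz) int32, 0 = background
    voxel_size: np.ndarray  # (3,) μm per axis
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    centroids: np.ndarray | None = None  # (K+1, 3) μm; row 0 unused

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("nuclei labels must be a 3D volume")
        if self.labels.min() < 0:
            raise ValueError("nuclei labels must be non-negative")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.centroids is None:
            self.centroids = self._compute_centroids()

    def _compute_centroids(self) -> np.ndarray:
        n = int(self.labels.max())
        cents = np.full((n + 1, 3), np.nan)
        if n:
            coms = ndimage.center_of_mass(
                np.ones_like(self.labels, dtype=np.uint8),
                self.labels,
                index=np.arange(1, n + 1),
            )
            # voxel-centre convention: index i spans [i*s, (i+1)*s)
            cents[1:] = (np.asarray(coms) + 0.5) * self.voxel_size + self.origin
        return cents

    @property
    def n_nuclei(self) -> int:
        ids = np.unique(self.labels)
        return int((ids > 0).sum())

    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def read_spots(
    path: str | Path,
    panel: GenePanel,
    *,
    columns: dict[str, str] | None = None,
    delimiter: str = ",",
    has_z: bool = True,
) -> SpotTable:
    """Read a delimited spot table into a :class:`SpotTable`.

    Parameters
    ----------
    columns
        Maps canonical names ``x``, ``y``, ``z``, ``gene`` to the file's
        column names. Defaults to identity.
    has_z
        When False, the z column is not required and z is set to 0.

    Genes absent from ``panel`` are dropped with a logged count.
    """
    cols = {"x": "x", "y": "y", "z": "z", "gene": "gene"}
    cols.update(columns or {})
    df = pd.read_csv(path, delimiter=delimiter)
    if df.empty:
        raise EmptyInputError(f"spot file {path} contains no rows")
    needed = ["x", "y", "gene"] + (["z"] if has_z else [])
    for key in needed:
        if cols[key] not in df.columns:
            raise FormatError(f"missing column {cols[key]!r} in {path}")
    name_to_idx = {n: i for i, n in enumerate(panel.names)}
    gene_idx = df[cols["gene"]].map(name_to_idx)
    dropped = int(gene_idx.isna().sum())
    if dropped:
        logger.warning("dropping %d spots with genes not in the panel", dropped)
    keep = gene_idx.notna().to_numpy()
    z = df[cols["z"]].to_numpy(float)[keep] if has_z else np.zeros(int(keep.sum()))
    xyz = np.column_stack(
        [df[cols["x"]].to_numpy(float)[keep], df[cols["y"]].to_numpy(float)[keep], z]
    )
    true_cell = None
    if "true_cell" in df.columns:
        true_cell = df["true_cell"].to_numpy(np.int64)[keep]
    return SpotTable(xyz, gene_idx.to_numpy(float)[keep].astype(np.int64), panel, true_cell)


def _pairwise_overlaps(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int, float]]:
    """Overlap of each labelled object in plane ``a`` with objects in ``b``.

    Returns (label_a, label_b, shared / min(size_a, size_b)) for every pair
    with non-zero intersection.
    """
    mask = (a > 0) & (b > 0)
    if not mask.any():
        return []
    pairs, counts = np.unique(
        np.stack([a[mask], b[mask]]).T, axis=0, return_counts=True
    )
    size_a = np.bincount(a.ravel())
    size_b = np.bincount(b.ravel())
    out = []
    for (la, lb), c in zip(pairs, counts):
        denom = min(size_a[la], size_b[lb])
        out.append((int(la), int(lb), float(c) / float(denom)))
    return out


def consolidate_nuclei_masks(
    planes: np.ndarray | list[np.ndarray],
    z_step: float,
    *,
    xy_size: float = 1.0,
    min_area: float = 10.0,
    overlap_frac: float = 0.30,
    min_z_extent: int = 5,
    origin: np.ndarray | None = None,
) -> NucleiSeeds:
    """Consolidate per-plane 2D nuclei masks into 3D seeds.

    2D masks smaller than ``min_area`` (μm²) are removed; masks in adjacent
    planes are merged into one 3D nucleus when the shared pixel count divided
    by the smaller mask's pixel count is at least ``overlap_frac``; merged
    nuclei spanning fewer than ``min_z_extent`` planes are removed. Survivors
    are relabelled 1..K.
    """
    planes = [np.asarray(p) for p in planes]
    shape0 = planes[0].shape
    if any(p.shape != shape0 for p in planes):
        raise ValueError("all 2D planes must share a shape")
    nz = len(planes)
    px_area = xy_size * xy_size
    min_pixels = min_area / px_area

    # area filter per plane
    filt = []
    for p in planes:
        p = p.copy()
        sizes = np.bincount(p.ravel())
        bad = np.flatnonzero(sizes < min_pixels)
        p[np.isin(p, bad) & (p > 0)] = 0
        filt.append(p)

    # give every (plane, label) a unique provisional id, then union-find merge
    offset = 0
    uids = []
    for p in filt:
        u = np.where(p > 0, p + offset, 0)
        offset += int(p.max()) if p.size and p.max() > 0 else 0
        uids.append(u)
    parent = {i: i for i in range(1, offset + 1)}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for z in range(nz - 1):
        for la, lb, frac in _pairwise_overlaps(uids[z], uids[z + 1]):
            if frac >= overlap_frac:
                union(la, lb)

    vol = np.stack(uids, axis=-1)  # (ny?, nx?, nz) -> axes (r, c, z)
    roots = np.zeros(offset + 1, dtype=np.int64)
    for i in range(1, offset + 1):
        roots[i] = find(i)
    vol = roots[vol]

    # z-extent filter
    keep_ids = []
    for lab in np.unique(vol):
        if lab == 0:
            continue
        zs = np.any(vol == lab, axis=(0, 1))
        if int(zs.sum()) >= min_z_extent:
            keep_ids.append(lab)
    relabel = np.zeros(vol.max() + 1, dtype=np.int32) if vol.max() > 0 else np.zeros(1, np.int32)
    for new, lab in enumerate(sorted(keep_ids), start=1):
        relabel[lab] = new
    vol = relabel[vol]

    voxel = np.array([xy_size, xy_size, z_step], dtype=float)
    return NucleiSeeds(
        labels=vol,
        voxel_size=voxel,
        origin=np.zeros(3) if origin is None else np.asarray(origin, float),
    )


def write_label_volume(path: str | Path, labels: np.ndarray, voxel_size, origin) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("labels", data=np.asarray(labels, np.int32), compression="gzip")
        d.attrs["voxel_size"] = np.asarray(voxel_size, float)
        d.attrs["origin"] = np.asarray(origin, float)


def read_label_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        d = f["labels"]
        return d[...], np.asarray(d.attrs["voxel_size"]), np.asarray(d.attrs["origin"])


def write_outputs(results, out_dir: str | Path) -> dict[str, Path]:
    """Write a finalized segmentation to ``out_dir``.

    Emits the label volume (HDF5), the cell × gene count matrix (wide TSV and
    MTX with cell/gene sidecars), the per-spot assignment table, and a JSON
    run manifest. ``results`` is a :class:`jointseg.model.SegmentationResults`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["labels"] = out / "labels.h5"
    write_label_volume(
        paths["labels"], results.labels, results.grid.pixel_size_vec, results.grid.origin
    )

    panel = results.spots.panel
    cells = results.cell_ids
    counts = pd.DataFrame(results.cell_counts, index=cells, columns=panel.names)
    counts.insert(0, "cell_type", [results.type_names[t] for t in results.cell_types])
    paths["counts"] = out / "cell_by_gene.tsv"
    counts.to_csv(paths["counts"], sep="\t", index_label="cell")

    paths["mtx"] = out / "counts.mtx"
    mmwrite(str(paths["mtx"]), sparse.csr_matrix(results.cell_counts))
    (out / "cells.txt").write_text("\n".join(str(c) for c in cells) + "\n")
    (out / "genes.txt").write_text("\n".join(panel.names) + "\n")

    paths["assignments"] = out / "spot_assignments.tsv"
    pd.DataFrame(
        {"spot": np.arange(len(results.spots)), "cell": results.spot_assignments}
    ).to_csv(paths["assignments"], sep="\t", index=False)

    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(results.manifest(), indent=2, default=str))
    return paths
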