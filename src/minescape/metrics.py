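"""Landscape-level pattern metrics with explicit patch delineation.

Nine metrics describe one categorical raster: mean patch size, patch
size coefficient of variation, landscape shape index (LSI),
area-weighted mean patch contiguity, contagion, mean Euclidean
nearest-neighbour distance (ENN), connectance, and Shannon's diversity
and evenness indices.

Conventions (the FRAGSTATS defaults): patches are 8-connected
components of a class; adjacency tabulations for contagion and edge
lengths use 4-neighbour cell sides; the landscape boundary counts as
edge for LSI but is excluded from contagion adjacencies; patch-to-patch
distances are between the centres of the closest cell pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

from . import constants as C
from .raster import LandUseGrid

_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)
_STRUCT_8 = np.ones((3, 3), dtype=int)

#: 3×3 contiguity template: orthogonal neighbours weight 2, diagonal 1,
#: centre 1 (template sum 13).
_CONTIG_TEMPLATE = np.array([[1, 2, 1], [2, 1, 2], [1, 2, 1]], dtype=float)


@dataclass
class Patch:
    id: int
    class_code: int
    rows: np.ndarray
    cols: np.ndarray
    area_hm2: float
    perimeter_m: float
    contiguity: float

    @property
    def n_cells(self) -> int:
        return len(self.rows)


@dataclass
class PatchSet:
    """Patches of one raster plus the landscape totals needed by the
    landscape-level metrics."""

    patches: list[Patch]
    cell_size: float
    total_area_hm2: float      # valid landscape area
    total_edge_m: float        # internal class edges, counted once
    boundary_edge_m: float     # valid-landscape outer boundary
    shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    def areas(self) -> np.ndarray:
        return np.array([p.area_hm2 for p in self.patches])

    def by_class(self) -> dict[int, list[Patch]]:
        out: dict[int, list[Patch]] = {}
        for p in self.patches:
            out.setdefault(p.class_code, []).append(p)
        return out


def _patch_perimeter(mask: np.ndarray, valid: np.ndarray, cell_size: float) -> float:
    """Cell sides adjacent to a different class, nodata, or the boundary."""
    exposed = 0
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neighbor_in = np.zeros_like(mask)
        if axis == 0:
            if shift == 1:
                neighbor_in[1:, :] = mask[:-1, :]
            else:
                neighbor_in[:-1, :] = mask[1:, :]
        else:
            if shift == 1:
                neighbor_in[:, 1:] = mask[:, :-1]
            else:
                neighbor_in[:, :-1] = mask[:, 1:]
        exposed += int(np.sum(mask & ~neighbor_in))
    return exposed * cell_size


def _patch_contiguity(mask: np.ndarray) -> float:
    """(mean 3×3 template score over patch cells − 1) / 12 ∈ [0, 1]."""
    score = ndimage.correlate(mask.astype(float), _CONTIG_TEMPLATE,
                              mode="constant", cval=0.0)
    mean_score = score[mask].mean()
    return float((mean_score - 1.0) / 12.0)


def delineate_patches(grid: LandUseGrid, connectivity: int = 8) -> PatchSet:
    """Connected components of each class under 4- or 8-adjacency."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    valid = grid.valid_mask
    if not valid.any():
        raise ValueError("empty raster: no valid cells")
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    cell_area = grid.cell_area_hm2
    patches: list[Patch] = []
    pid = 0
    for code in sorted(grid.class_counts()):
        class_mask = (grid.data == code) & valid
        labels, n = ndimage.label(class_mask, structure=structure)
        for k in range(1, n + 1):
            pmask = labels == k
            rows, cols = np.nonzero(pmask)
            pid += 1
            patches.append(Patch(
                id=pid,
                class_code=code,
                rows=rows,
                cols=cols,
                area_hm2=len(rows) * cell_area,
                perimeter_m=_patch_perimeter(pmask, valid, grid.cell_size),
                contiguity=_patch_contiguity(pmask),
            ))
    data = grid.data
    internal = 0
    for a, b in (((slice(None, -1), slice(None)), (slice(1, None), slice(None))),
                 ((slice(None), slice(None, -1)), (slice(None), slice(1, None)))):
        d1, d2 = data[a], data[b]
        v1, v2 = valid[a], valid[b]
        internal += int(np.sum(v1 & v2 & (d1 != d2)))
    boundary = _patch_perimeter(valid, valid, grid.cell_size)
    return PatchSet(
        patches=patches,
        cell_size=grid.cell_size,
        total_area_hm2=float(valid.sum()) * cell_area,
        total_edge_m=internal * grid.cell_size,
        boundary_edge_m=boundary,
        shape=grid.shape,
    )


def mean_patch_size(p: PatchSet) -> float:
    """Landscape mean patch size, hm²: total area / number of patches."""
    if p.n_patches < 1:
        raise ValueError("at least one patch required")
    return p.total_area_hm2 / p.n_patches


def patch_size_cv(p: PatchSet) -> float:
    """Patch size coefficient of variation, %: population SD / mean."""
    if p.n_patches < 2:
        raise ValueError("CV needs at least two patches")
    areas = p.areas()
    return float(100.0 * areas.std() / areas.mean())


def landscape_shape_index(p: PatchSet) -> float:
    """LSI = 0.25·E*/√A with E* the total edge including the landscape
    boundary; equals 1 for a single-class square landscape."""
    if p.total_area_hm2 <= 0:
        raise ValueError("positive landscape area required")
    e_star = p.total_edge_m + p.boundary_edge_m
    area_m2 = p.total_area_hm2 * 10_000.0
    return float(0.25 * e_star / np.sqrt(area_m2))


def contiguity_am(p: PatchSet) -> float:
    """Area-weighted mean patch contiguity index in [0, 1]."""
    if p.n_patches < 1:
        raise ValueError("at least one patch required")
    areas = p.areas()
    vals = np.array([q.contiguity for q in p.patches])
    return float((vals * areas).sum() / areas.sum())


def contagion(grid: LandUseGrid) -> float:
    """Contagion, %: overall clumpiness from class proportions and
    double-counted 4-neighbour like/unlike cell adjacencies; boundary
    and nodata adjacencies excluded.  100 for a single-class raster."""
    valid = grid.valid_mask
    vals = grid.data[valid]
    classes = np.unique(vals)
    m = len(classes)
    if m == 0:
        raise ValueError("empty raster")
    if m == 1:
        return 100.0
    g = np.zeros((m, m))
    data = grid.data
    for a, b in (((slice(None, -1), slice(None)), (slice(1, None), slice(None))),
                 ((slice(None), slice(None, -1)), (slice(None), slice(1, None)))):
        d1, d2 = data[a].ravel(), data[b].ravel()
        ok = valid[a].ravel() & valid[b].ravel()
        i = np.searchsorted(classes, d1[ok])
        k = np.searchsorted(classes, d2[ok])
        np.add.at(g, (i, k), 1)
        np.add.at(g, (k, i), 1)
    counts = np.array([(vals == c).sum() for c in classes], dtype=float)
    P = counts / counts.sum()
    row_tot = g.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = P[:, None] * np.where(row_tot > 0, g / row_tot, 0.0)
    nz = q > 0
    s = float((q[nz] * np.log(q[nz])).sum())
    return float((1.0 + s / (2.0 * np.log(m))) * 100.0)


def _boundary_cells(patch: Patch, shape: tuple[int, int]) -> np.ndarray:
    """Coordinates of patch cells with at least one 4-neighbour outside
    the patch (the nearest inter-patch cell pair involves these)."""
    mask = np.zeros(shape, dtype=bool)
    mask[patch.rows, patch.cols] = True
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT_4.astype(bool),
                                    border_value=0)
    rows, cols = np.nonzero(mask & ~eroded)
    return np.column_stack([rows, cols]).astype(float)


def class_patch_distances(p: PatchSet) -> dict[int, np.ndarray]:
    """Per class with ≥ 2 patches: symmetric matrix of pairwise
    nearest-cell-centre distances (m)."""
    out: dict[int, np.ndarray] = {}
    for code, patches in p.by_class().items():
        n = len(patches)
        if n < 2:
            continue
        coords = [_boundary_cells(q, p.shape) for q in patches]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = cdist(coords[i], coords[j]).min() * p.cell_size
        out[code] = d
    return out


def enn_mn(p: PatchSet, distances: dict[int, np.ndarray] | None = None) -> float:
    """Mean Euclidean nearest-neighbour distance, m, averaged over all
    patches whose class has at least one other patch."""
    distances = class_patch_distances(p) if distances is None else distances
    if not distances:
        raise ValueError("ENN undefined: no class has two or more patches")
    nn = []
    for d in distances.values():
        dd = d.copy()
        np.fill_diagonal(dd, np.inf)
        nn.extend(dd.min(axis=1))
    return float(np.mean(nn))


def connectance(p: PatchSet, threshold: float,
                distances: dict[int, np.ndarray] | None = None) -> float:
    """Connectance, %: same-class patch pairs within the threshold
    distance over all same-class pairs."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    distances = class_patch_distances(p) if distances is None else distances
    if not distances:
        raise ValueError("connectance undefined: no class has two or more patches")
    joined = possible = 0
    for d in distances.values():
        n = d.shape[0]
        iu = np.triu_indices(n, k=1)
        possible += len(iu[0])
        joined += int((d[iu] <= threshold).sum())
    return float(100.0 * joined / possible)


def shdi(grid: LandUseGrid) -> float:
    """Shannon's diversity index (nats) over class area proportions."""
    vals = grid.data[grid.valid_mask]
    if vals.size == 0:
        raise ValueError("empty raster")
    _, counts = np.unique(vals, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def shei(grid: LandUseGrid) -> float:
    """Shannon's evenness index: SHDI / ln(m); 0 for a one-class map."""
    vals = grid.data[grid.valid_mask]
    m = len(np.unique(vals))
    if m <= 1:
        return 0.0
    return shdi(grid) / float(np.log(m))


@dataclass
class MetricsReport:
    """The nine landscape-level metric values for one map."""

    mean_patch_size: float
    patch_size_cv: float
    landscape_shape_index: float
    contiguity_am: float
    contagion: float
    enn_mn: float
    connectance: float
    shdi: float
    shei: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)

    def to_series(self, name: str = "value") -> pd.Series:
        return pd.Series(self.to_dict(), name=name)


def compute_metrics(grid: LandUseGrid, connectivity: int = 8,
                    connect_threshold: float | None = None) -> MetricsReport:
    """All nine metrics for one raster.

    The connectance threshold defaults to the landscape mean ENN (the
    ranking then tracks ENN).  On maps where ENN is undefined (every
    class a single patch) ENN and connectance are reported as NaN.
    """
    p = delineate_patches(grid, connectivity=connectivity)
    distances = class_patch_distances(p)
    if distances:
        enn = enn_mn(p, distances)
        thr = connect_threshold if connect_threshold is not None else enn
        conn = connectance(p, thr, distances)
    else:
        enn = float("nan")
        conn = float("nan")
    return MetricsReport(
        mean_patch_size=mean_patch_size(p),
        patch_size_cv=patch_size_cv(p) if p.n_patches >= 2 else float("nan"),
        landscape_shape_index=landscape_shape_index(p),
        contiguity_am=contiguity_am(p),
        contagion=contagion(grid),
        enn_mn=enn,
        connectance=conn,
        shdi=shdi(grid),
        shei=shei(grid),
    )
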