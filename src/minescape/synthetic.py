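"""Synthetic landscape generator.

Produces base-year land-use rasters, driving-factor stacks with a known
logit structure, and abandoned-mine-land (AML) patch attribute tables,
so the whole demand→allocation→metrics pipeline is testable without the
original survey rasters.

The generator works in three stages:

1. Fifteen driving factors are built as a deterministic planar gradient
   (direction varying by factor) plus Gaussian-smoothed noise, then
   standardised.  Smoothing radius = ``clump_scale`` cells.
2. Each class gets a linear utility ``β0 + Σ βk·Xk`` from the
   generator-truth coefficient matrix ``true_betas`` plus smoothed
   Gumbel noise; cells are assigned to classes by a deterministic
   capacity-constrained greedy (cells in descending best-utility order
   take their best class with spare capacity), so per-class cell counts
   match the requested proportions exactly.
3. AML cells are carved explicitly as ``n_aml_patches`` seeded regions
   grown by AML utility, and each resulting patch receives a reclamation
   attribute record drawn uniformly over the suitability grading
   intervals.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import constants as C
from .raster import DrivingFactorStack, LandUseGrid

N_FACTORS = 15
FACTOR_NAMES = tuple(f"X{i + 1}" for i in range(N_FACTORS))

SURFACE_MATERIALS = ("loam_sandy_loam", "rock_soil_mixture", "sand_gravel")
IRRIGATION_LEVELS = ("fully_satisfied", "basically_satisfied", "without_irrigation")
DAMAGE_LEVELS = ("light", "moderate", "severe")


def _default_true_betas() -> np.ndarray:
    """Generator-truth coefficients, shape (8 classes, 1 + 15 factors).

    Each class is loaded on a few ecologically sensible factors
    (distances enter negatively when proximity favours the class);
    zeros elsewhere keep the sign-recovery check well defined.
    """
    b = np.zeros((8, N_FACTORS + 1))

    def s(code: int, **kw: float) -> None:
        for name, v in kw.items():
            b[code - 1, int(name[1:])] = v

    s(C.CULTIVATED, X1=-1.2, X2=-1.0, X8=1.2, X9=0.8)
    s(C.GARDEN, X2=-0.8, X5=-1.0, X8=0.8)
    s(C.FOREST, X1=1.0, X3=0.8, X15=1.0)
    s(C.GRASSLAND, X1=0.8, X14=0.8)
    s(C.CONSTRUCTION, X3=-1.2, X6=-0.8, X9=1.0)
    s(C.AML, X4=-0.8, X12=1.2)
    s(C.WATER, X1=-0.8, X5=-1.5)
    s(C.UNUTILIZED, X2=1.0, X8=-0.8)
    return b


DEFAULT_TRUE_BETAS = _default_true_betas()

_DEFAULT_PROPORTIONS = tuple(C.AREAS_2007[c] / C.TOTAL_AREA for c in C.CLASS_CODES)


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic landscape realisation.

    n_active_cells (optional) restricts the landscape to the first
    n cells in row-major order, padding the remainder with nodata —
    used to emulate study areas whose cell count is not a product of
    two convenient grid dimensions.  Same seed ⇒ bit-identical output.
    """

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 100.0
    class_proportions: tuple[float, ...] = _DEFAULT_PROPORTIONS
    n_active_cells: int | None = None
    n_aml_patches: int = 93
    clump_scale: float = 4.0
    noise_scale: float = 0.8
    true_betas: np.ndarray = field(default_factory=lambda: DEFAULT_TRUE_BETAS.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (8,):
            raise ValueError("class_proportions must have 8 entries")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if (props < 0).any():
            raise ValueError("class_proportions must be non-negative")
        self.class_proportions = tuple(props)
        n_cells = self.n_rows * self.n_cols
        if self.n_active_cells is not None:
            if not 0 < self.n_active_cells <= n_cells:
                raise ValueError("n_active_cells must be in (0, n_rows*n_cols]")
        self.true_betas = np.asarray(self.true_betas, dtype=float)
        if self.true_betas.shape != (8, N_FACTORS + 1):
            raise ValueError("true_betas must have shape (8, 16)")
        if props[C.AML - 1] > 0 and self.n_aml_patches < 1:
            raise ValueError("n_aml_patches must be >= 1 when AML has positive proportion")
        aml_cells = props[C.AML - 1] * self.n_cells
        if props[C.AML - 1] > 0 and self.n_aml_patches > aml_cells:
            raise ValueError("grid too small to host n_aml_patches")

    @property
    def n_cells(self) -> int:
        return self.n_active_cells if self.n_active_cells is not None else self.n_rows * self.n_cols


def mentougou_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Study-scale configuration: 46,634 active 1-ha cells with the
    base-year class areas, on a 214×218 grid padded with 18 nodata cells."""
    kw = dict(n_rows=214, n_cols=218, n_active_cells=C.TOTAL_AREA, seed=seed)
    kw.update(overrides)
    return SyntheticConfig(**kw)


@dataclass
class AMLPatch:
    id: int
    rows: np.ndarray
    cols: np.ndarray
    area_hm2: float
    attrs: dict

    @property
    def n_cells(self) -> int:
        return len(self.rows)


@dataclass
class AMLPatchSet:
    patches: list[AMLPatch]

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    @property
    def total_area_hm2(self) -> float:
        return sum(p.area_hm2 for p in self.patches)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.patches:
            rec = {"patch_id": p.id, "area_hm2": p.area_hm2, "n_cells": p.n_cells}
            rec.update(p.attrs)
            rows.append(rec)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative float targets to ints summing exactly to total."""
    targets = np.asarray(targets, dtype=float)
    if (targets < 0).any():
        raise ValueError("targets must be non-negative")
    base = np.floor(targets).astype(int)
    short = total - int(base.sum())
    if short < 0:
        raise ValueError("targets exceed total")
    frac = targets - base
    # deterministic: largest fractional remainder first, index breaks ties
    order = np.lexsort((np.arange(len(targets)), -frac))
    base[order[:short]] += 1
    return base


def _generate_factors(config: SyntheticConfig, rng: np.random.Generator) -> DrivingFactorStack:
    rows, cols = config.n_rows, config.n_cols
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rr = (rr - rr.mean()) / max(rows, 1)
    cc = (cc - cc.mean()) / max(cols, 1)
    layers = np.empty((N_FACTORS, rows, cols))
    for k in range(N_FACTORS):
        angle = 2 * np.pi * k / N_FACTORS
        gradient = np.cos(angle) * rr + np.sin(angle) * cc
        noise = rng.standard_normal((rows, cols))
        noise = ndimage.gaussian_filter(noise, sigma=config.clump_scale)
        layer = gradient + noise / max(noise.std(), 1e-12)
        layers[k] = (layer - layer.mean()) / max(layer.std(), 1e-12)
    return DrivingFactorStack(layers, FACTOR_NAMES, cell_size=config.cell_size)


def true_probabilities(config: SyntheticConfig, factors: DrivingFactorStack,
                       mask: np.ndarray) -> dict[int, np.ndarray]:
    """Per-class binomial-logit probabilities implied by true_betas,
    over the valid cells (returned as flat arrays keyed by class code)."""
    X = factors.design_matrix(mask)
    out = {}
    for code in C.CLASS_CODES:
        b = config.true_betas[code - 1]
        eta = b[0] + X @ b[1:]
        out[code] = 1.0 / (1.0 + np.exp(-eta))
    return out


def _carve_aml(utility: np.ndarray, active: np.ndarray, n_patches: int,
               n_cells_target: int, rng: np.random.Generator) -> np.ndarray:
    """Grow n_patches AML regions by descending AML utility.

    Returns a boolean mask of AML cells with exactly n_cells_target True
    entries.  Patches grown later may wrap around earlier ones, so the
    realised number of connected components can be below n_patches.
    """
    rows, cols = utility.shape
    aml_mask = np.zeros_like(active, dtype=bool)
    if n_cells_target == 0:
        return aml_mask
    # patch target sizes: gamma weights, every patch at least one cell
    weights = rng.gamma(2.0, size=n_patches)
    sizes = largest_remainder(weights / weights.sum() * n_cells_target, n_cells_target)
    sizes = np.maximum(sizes, 1)
    while sizes.sum() > n_cells_target:
        sizes[int(np.argmax(sizes))] -= 1
    # seeds: best-utility cells kept pairwise distant; the separation of
    # two seeds scales with the radii their patches would have if round,
    # so growth fronts rarely touch
    flat_order = np.argsort(-utility, axis=None, kind="stable")
    radii = np.sqrt(sizes / np.pi)
    margin = 2.0
    seeds: list[tuple[int, int]] = []
    while len(seeds) < n_patches:
        seeds.clear()
        for idx in flat_order:
            r, c = divmod(int(idx), cols)
            if not active[r, c]:
                continue
            k = len(seeds)
            ok = True
            for j, (sr, sc) in enumerate(seeds):
                d_min = margin * (radii[k] + radii[j]) + 2.0
                if (r - sr) ** 2 + (c - sc) ** 2 < d_min**2:
                    ok = False
                    break
            if ok:
                seeds.append((r, c))
                if len(seeds) == n_patches:
                    break
        if len(seeds) < n_patches:
            margin *= 0.7
            if margin < 0.05:
                raise ValueError("grid too small to host n_aml_patches")
    taken = np.zeros_like(active, dtype=bool)
    neigh = ((-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1))

    def grow(seed: tuple[int, int], target: int) -> int:
        grown = 0
        heap: list[tuple[float, int, int]] = []
        sr, sc = seed
        if taken[sr, sc]:
            return 0
        heapq.heappush(heap, (-utility[sr, sc], sr, sc))
        pending = {(sr, sc)}
        while heap and grown < target:
            _, r, c = heapq.heappop(heap)
            if taken[r, c]:
                continue
            taken[r, c] = aml_mask[r, c] = True
            grown += 1
            for dr, dc in neigh:
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols and active[nr, nc] \
                        and not taken[nr, nc] and (nr, nc) not in pending:
                    pending.add((nr, nc))
                    heapq.heappush(heap, (-utility[nr, nc], nr, nc))
        return grown

    total = 0
    for seed, size in zip(seeds, sizes):
        total += grow(seed, int(size))
    # top off any deficit (enclosed patches) from the union frontier
    while total < n_cells_target:
        frontier = ndimage.binary_dilation(aml_mask, np.ones((3, 3), bool)) & active & ~aml_mask
        if not frontier.any():
            raise ValueError("cannot place requested AML area on the active grid")
        idx = np.argmax(np.where(frontier, utility, -np.inf))
        r, c = divmod(int(idx), cols)
        aml_mask[r, c] = taken[r, c] = True
        total += 1
    return aml_mask


def _sample_patch_attrs(rng: np.random.Generator) -> dict:
    """One attribute record, uniform over the suitability grading intervals."""
    return {
        "slope_deg": float(rng.uniform(0.0, 20.0)),
        "surface_material": str(rng.choice(SURFACE_MATERIALS)),
        "soil_organic_matter_pct": float(rng.uniform(0.1, 2.0)),
        "soil_thickness_cm": float(rng.uniform(10.0, 120.0)),
        "irrigation": str(rng.choice(IRRIGATION_LEVELS)),
        "road_distance_m": float(rng.uniform(0.0, 8000.0)),
        "damage": str(rng.choice(DAMAGE_LEVELS)),
    }


def delineate_aml_patches(grid: LandUseGrid, attrs_rng: np.random.Generator | None = None,
                          attr_records: list[dict] | None = None) -> AMLPatchSet:
    """AML patches as 8-connected components of the AML class."""
    mask = (grid.data == C.AML) & grid.valid_mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    patches = []
    for pid in range(1, n + 1):
        rows, cols = np.nonzero(labels == pid)
        if attr_records is not None:
            attrs = attr_records[pid - 1]
        elif attrs_rng is not None:
            attrs = _sample_patch_attrs(attrs_rng)
        else:
            attrs = {}
        patches.append(AMLPatch(pid, rows, cols, len(rows) * grid.cell_area_hm2, attrs))
    return AMLPatchSet(patches)


def generate_landscape(config: SyntheticConfig) -> tuple[LandUseGrid, DrivingFactorStack, AMLPatchSet]:
    """Generate one synthetic landscape realisation.

    Per-class cell counts match class_proportions · n_cells exactly
    (largest-remainder rounding); factor rasters are standardised; the
    class labels follow the generator-truth utilities so that fitting a
    one-vs-rest logit on the output recovers the signs of true_betas.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.n_rows, config.n_cols
    factors = _generate_factors(config, rng)

    active = np.ones((rows, cols), dtype=bool)
    if config.n_active_cells is not None:
        flat = np.zeros(rows * cols, dtype=bool)
        flat[: config.n_active_cells] = True
        active = flat.reshape(rows, cols)

    n_active = int(active.sum())
    counts = largest_remainder(np.asarray(config.class_proportions) * n_active, n_active)

    # class utilities: truth logit score + smoothed Gumbel noise
    X = factors.data.reshape(N_FACTORS, -1).T  # all cells × factors
    utilities = np.empty((rows * cols, 8))
    for code in C.CLASS_CODES:
        b = config.true_betas[code - 1]
        utilities[:, code - 1] = b[0] + X @ b[1:]
    noise = rng.gumbel(scale=config.noise_scale, size=(rows * cols, 8))
    for u in range(8):
        layer = ndimage.gaussian_filter(noise[:, u].reshape(rows, cols),
                                        sigma=config.clump_scale / 2.0)
        utilities[:, u] += layer.ravel()

    data = np.full((rows, cols), -9999, dtype=np.int32)

    # carve AML patches first so their count and geometry are controlled
    aml_count = int(counts[C.AML - 1])
    if aml_count > 0:
        aml_util = utilities[:, C.AML - 1].reshape(rows, cols)
        aml_mask = _carve_aml(aml_util, active, config.n_aml_patches, aml_count, rng)
        data[aml_mask] = C.AML
    else:
        aml_mask = np.zeros((rows, cols), dtype=bool)

    # capacity-constrained greedy for the remaining classes
    remaining = counts.copy()
    remaining[C.AML - 1] = 0
    free = active & ~aml_mask
    free_idx = np.nonzero(free.ravel())[0]
    util_free = utilities[free_idx][:, :]
    util_free[:, C.AML - 1] = -np.inf
    order = np.argsort(-util_free.max(axis=1), kind="stable")
    pref = np.argsort(-util_free, axis=1, kind="stable")
    flat_data = data.ravel()
    for j in order:
        for u in pref[j]:
            if remaining[u] > 0:
                flat_data[free_idx[j]] = u + 1
                remaining[u] -= 1
                break

    grid = LandUseGrid(data, cell_size=config.cell_size)
    attr_records = None
    if aml_count > 0:
        mask = (grid.data == C.AML)
        _, n_patches = ndimage.label(mask, structure=np.ones((3, 3), int))
        attr_records = [_sample_patch_attrs(rng) for _ in range(n_patches)]
    patchset = delineate_aml_patches(grid, attr_records=attr_records)
    return grid, factors, patchset


def sample_logit_labels(factors: DrivingFactorStack, betas: np.ndarray,
                        seed: int = 0, mask: np.ndarray | None = None) -> np.ndarray:
    """Draw Bernoulli labels from the exact binomial-logit model
    P = sigmoid(β0 + Σ βk Xk) — the data-generating process used by the
    coefficient-recovery checks."""
    betas = np.asarray(betas, dtype=float)
    if mask is None:
        mask = np.ones(factors.data.shape[1:], dtype=bool)
    X = factors.design_matrix(mask)
    p = 1.0 / (1.0 + np.exp(-(betas[0] + X @ betas[1:])))
    rng = np.random.default_rng(seed)
    return (rng.random(p.shape) < p).astype(int)


def forward_reference(config: SyntheticConfig, rules, trajectory) -> LandUseGrid:
    """Horizon-year "future truth" map: the allocation engine run with
    the generator's true coefficients, used as the reference map in
    agreement (Kappa) tests."""
    from .allocation import simulate

    grid, factors, _ = generate_landscape(config)
    probs = true_probabilities(config, factors, grid.valid_mask)
    maps = simulate(grid, trajectory, rules, probs)
    return maps[-1]
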