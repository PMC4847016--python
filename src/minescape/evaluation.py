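"""Validation and reporting: map agreement (Cohen's Kappa),
demand-vs-simulation relative error, and transition cross-tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as C
from .demand import round_half_up
from .raster import LandUseGrid


@dataclass
class AgreementReport:
    """Cell-by-cell agreement between two categorical maps."""

    confusion: pd.DataFrame   # rows: map a, cols: map b, cell counts
    overall_agreement: float  # p_o
    expected_agreement: float  # p_e
    kappa: float


def _joint_valid(a: LandUseGrid, b: LandUseGrid) -> np.ndarray:
    if a.shape != b.shape:
        raise ValueError(f"raster shapes differ: {a.shape} vs {b.shape}")
    return a.valid_mask & b.valid_mask


def kappa(a: LandUseGrid, b: LandUseGrid) -> AgreementReport:
    """Unweighted Cohen's Kappa over jointly valid cells.

    Kappa = (p_o − p_e)/(1 − p_e); equals 1 iff the maps agree on every
    valid cell (returned directly in that case, where p_e may be 1 too).
    """
    mask = _joint_valid(a, b)
    va, vb = a.data[mask], b.data[mask]
    if va.size == 0:
        raise ValueError("no jointly valid cells")
    codes = np.union1d(np.unique(va), np.unique(vb))
    k = len(codes)
    ia = np.searchsorted(codes, va)
    ib = np.searchsorted(codes, vb)
    conf = np.zeros((k, k), dtype=np.int64)
    np.add.at(conf, (ia, ib), 1)
    n = conf.sum()
    p_o = float(np.trace(conf)) / n
    p_e = float((conf.sum(axis=1) * conf.sum(axis=0)).sum()) / (n * n)
    kap = 1.0 if p_o == 1.0 else (p_o - p_e) / (1.0 - p_e)
    table = pd.DataFrame(conf, index=codes, columns=codes)
    return AgreementReport(table, p_o, p_e, float(kap))


def relative_error(demand: dict[int, float], simulated: dict[int, float]) -> dict[int, float]:
    """Per-class relative error, %: 100·(simulated − demand)/demand,
    rounded half-up to 2 decimals (negative when the simulation
    under-shoots demand)."""
    out = {}
    for code, d in demand.items():
        if d <= 0:
            raise ValueError(f"demand for class {code} must be strictly positive")
        out[code] = round_half_up(100.0 * (simulated[code] - d) / d)
    return out


@dataclass
class TransitionTable:
    """Origin × destination class areas (hm²) between two maps."""

    areas: pd.DataFrame  # rows: origin class, cols: destination class

    def row_sums(self) -> pd.Series:
        return self.areas.sum(axis=1)

    def column_sums(self) -> pd.Series:
        return self.areas.sum(axis=0)


def transition_crosstab(origin: LandUseGrid, destination: LandUseGrid,
                        focus: int | None = None) -> TransitionTable:
    """Joint per-cell tabulation converted to hm²; focus restricts the
    rows to one origin class (e.g. AML for a reclamation overlay)."""
    mask = _joint_valid(origin, destination)
    vo, vd = origin.data[mask], destination.data[mask]
    codes = np.union1d(np.unique(vo), np.unique(vd))
    k = len(codes)
    io = np.searchsorted(codes, vo)
    id_ = np.searchsorted(codes, vd)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (io, id_), 1)
    areas = pd.DataFrame(counts * origin.cell_area_hm2, index=codes, columns=codes)
    if focus is not None:
        if focus not in areas.index:
            raise ValueError(f"origin class {focus} absent from the origin map")
        areas = areas.loc[[focus]]
    return TransitionTable(areas)
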