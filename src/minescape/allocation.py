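"""Spatial allocation module (CLUE-S style).

Per-class location suitability comes from one-vs-rest binomial logit
models on the driving-factor stack, ln(P/(1−P)) = β0 + Σ βk·Xk.  Each
yearly step assigns every cell the allowed class with the largest total
conversion probability

    TPROP(i, u) = P(i, u) + ELAS(u) + ITER(u)

where ELAS is the conversion elasticity in [0, 1] (by default granted
only to the cell's incumbent class, as a stability bonus) and ITER is a
per-class competition offset adjusted iteratively — raised for
under-allocated and lowered for over-allocated classes — until every
class area is within tolerance of its demand.

Conversion rules: an 8×8 binary matrix of allowed transitions (diagonal
always 1), no class may convert *into* abandoned mine land, and
construction land and water are irreversible (their rows allow only
self-transition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from . import constants as C
from .raster import DrivingFactorStack, LandUseGrid


class AllocationError(RuntimeError):
    """Demand could not be met within tolerance in max_iter sweeps."""


DEFAULT_ELAS = {
    C.CULTIVATED: 0.6,
    C.GARDEN: 0.6,
    C.FOREST: 0.8,
    C.GRASSLAND: 0.5,
    C.CONSTRUCTION: 1.0,
    C.AML: 0.2,
    C.WATER: 1.0,
    C.UNUTILIZED: 0.3,
}


def default_transition_matrix() -> np.ndarray:
    """All conversions allowed except into AML; construction and water
    rows are self-only (irreversible classes)."""
    m = np.ones((8, 8), dtype=int)
    m[:, C.AML - 1] = 0
    for code in (C.CONSTRUCTION, C.WATER):
        m[code - 1, :] = 0
        m[code - 1, code - 1] = 1
    np.fill_diagonal(m, 1)
    return m


@dataclass
class TransitionRules:
    """Conversion elasticities and allowed-transition matrix.

    elas maps class code → ELAS in [0, 1] (0 = easy conversion,
    1 = irreversible change); matrix[from−1, to−1] ∈ {0, 1}.
    """

    elas: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_ELAS))
    matrix: np.ndarray = field(default_factory=default_transition_matrix)
    protected: tuple[int, ...] = (C.CONSTRUCTION, C.WATER)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if self.matrix.shape != (8, 8):
            raise ValueError("transition matrix must be 8×8")
        if not np.all(np.diag(self.matrix) == 1):
            raise ValueError("transition matrix diagonal must be 1 (class may keep itself)")
        off_into_aml = self.matrix[:, C.AML - 1].copy()
        off_into_aml[C.AML - 1] = 0
        if off_into_aml.any():
            raise ValueError("no class may convert into AML")
        for code in self.protected:
            row = self.matrix[code - 1].copy()
            row[code - 1] = 0
            if row.any():
                raise ValueError(f"{C.CLASS_NAMES[code]} must be self-transition only")
        for code, e in self.elas.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"ELAS for class {code} outside [0, 1]")


@dataclass
class LogitModel:
    """One-vs-rest binomial logit for a land-use class."""

    class_code: int
    beta: np.ndarray            # (1 + n_factors,), intercept first
    bse: np.ndarray | None      # standard errors; None for regularized fallback
    factor_names: tuple[str, ...]
    regularized: bool = False

    def predict(self, factors: DrivingFactorStack, mask: np.ndarray | None = None) -> np.ndarray:
        """Fitted probabilities over the mask (flat array), clipped into (0, 1)."""
        if mask is None:
            mask = np.ones(factors.data.shape[1:], dtype=bool)
        X = factors.design_matrix(mask)
        eta = self.beta[0] + X @ self.beta[1:]
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        return np.clip(p, 1e-12, 1 - 1e-12)


def fit_logit(grid: LandUseGrid, factors: DrivingFactorStack, class_code: int) -> LogitModel:
    """Maximum-likelihood one-vs-rest logit of class presence on the
    driving factors over all valid cells.

    On (quasi-)separation or non-convergence the fit falls back to an
    L2-regularized logistic regression and is flagged ``regularized``.
    """
    mask = grid.valid_mask
    y = (grid.data[mask] == class_code).astype(int)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError(
            f"class {class_code} needs at least 2 presence and 2 absence cells"
        )
    X = factors.design_matrix(mask)
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False):
            raise RuntimeError("logit MLE did not converge")
        beta = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(bse))):
            raise RuntimeError("non-finite logit coefficients")
        return LogitModel(class_code, beta, bse, factors.names)
    except Exception:
        clf = LogisticRegression(C=1e4, max_iter=2000)
        clf.fit(X, y)
        beta = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        return LogitModel(class_code, beta, None, factors.names, regularized=True)


def fit_all_logits(grid: LandUseGrid, factors: DrivingFactorStack) -> dict[int, LogitModel]:
    return {code: fit_logit(grid, factors, code)
            for code in C.CLASS_CODES if (grid.data[grid.valid_mask] == code).sum() >= 2}


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic ROC area with midrank tie handling."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both outcome labels present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auc(model: LogitModel, grid: LandUseGrid, factors: DrivingFactorStack) -> float:
    """ROC area of a class model against the observed class map."""
    mask = grid.valid_mask
    labels = (grid.data[mask] == model.class_code).astype(int)
    return rank_auc(labels, model.predict(factors, mask))


def tprop(p: float | np.ndarray, elas: float, iter_u: float) -> float | np.ndarray:
    """Total conversion probability: additive combination of location
    probability, conversion elasticity and the competition offset."""
    return p + elas + iter_u


def models_to_dataframe(models: dict[int, LogitModel]) -> pd.DataFrame:
    rows = []
    for code, m in sorted(models.items()):
        rec = {"class_code": code, "class": C.CLASS_NAMES[code],
               "regularized": m.regularized, "beta0": m.beta[0]}
        for name, b in zip(m.factor_names, m.beta[1:]):
            rec[f"beta_{name}"] = b
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class AllocationState:
    """Diagnostics of one allocation step."""

    iterations: int
    converged: bool
    iter_offsets: dict[int, float]
    allocated: dict[int, int]
    demanded: dict[int, int]


def _check_satisfiable(counts: dict[int, int], demand: dict[int, int],
                       rules: TransitionRules, tol: dict[int, float]) -> None:
    m = rules.matrix
    for code in C.CLASS_CODES:
        cur = counts.get(code, 0)
        d = demand.get(code, 0)
        row = m[code - 1].copy()
        row[code - 1] = 0
        col = m[:, code - 1].copy()
        col[code - 1] = 0
        can_lose = bool(row.any())
        can_gain = bool(col.any())
        if not can_lose and d < cur - tol[code]:
            raise ValueError(
                f"demand for {C.CLASS_NAMES[code]} ({d}) below its fixed area "
                f"({cur}) but the class cannot convert away"
            )
        if not can_gain and d > cur + tol[code]:
            raise ValueError(
                f"demand for {C.CLASS_NAMES[code]} ({d}) above its current area "
                f"({cur}) but no class may convert into it"
            )


def allocate_step(
    current: LandUseGrid,
    demand_cells: dict[int, int],
    rules: TransitionRules,
    probabilities: dict[int, np.ndarray],
    tolerance: float = 0.005,
    max_iter: int = 2000,
    eta: float = 0.05,
    elas_mode: str = "incumbent",
) -> tuple[LandUseGrid, AllocationState]:
    """Allocate one year's demand over the raster.

    probabilities maps class code → flat P array over valid cells (the
    logit fits).  tolerance is the per-class relative demand tolerance
    (never below one cell).  elas_mode "incumbent" adds ELAS only for a
    cell's current class; "all" adds it for every candidate class.
    """
    if elas_mode not in ("incumbent", "all"):
        raise ValueError("elas_mode must be 'incumbent' or 'all'")
    mask = current.valid_mask
    cur = current.data[mask]
    n_cells = cur.size
    demand = {code: int(demand_cells.get(code, 0)) for code in C.CLASS_CODES}
    if sum(demand.values()) != n_cells:
        raise ValueError(
            f"demand ({sum(demand.values())} cells) must sum to the landscape "
            f"area ({n_cells} cells)"
        )
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    # relative tolerance, never below one cell; tolerance 0 demands exact areas
    tol = {code: (max(1.0, tolerance * demand[code]) if tolerance > 0 else 0.0)
           for code in C.CLASS_CODES}
    _check_satisfiable(
        {c: int((cur == c).sum()) for c in C.CLASS_CODES}, demand, rules, tol)

    # base scores: P + ELAS, with disallowed transitions masked out
    scores = np.full((n_cells, 8), -np.inf)
    for code in C.CLASS_CODES:
        u = code - 1
        if demand[code] == 0 and not (cur == code).any():
            continue
        p = probabilities.get(code)
        if p is None:
            p = np.zeros(n_cells)
        col = np.asarray(p, dtype=float).copy()
        if elas_mode == "all":
            col += rules.elas.get(code, 0.0)
        else:
            col[cur == code] += rules.elas.get(code, 0.0)
        allowed = rules.matrix[cur - 1, u].astype(bool)
        col[~allowed] = -np.inf
        scores[:, u] = col

    demand_vec = np.array([demand[c] for c in C.CLASS_CODES], dtype=float)
    iter_vec = np.zeros(8)
    eta_vec = np.full(8, eta)
    prev_gap = np.zeros(8)
    assign = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        assign = np.argmax(scores + iter_vec, axis=1)
        counts = np.bincount(assign, minlength=8).astype(float)
        gap = demand_vec - counts
        tol_vec = np.array([tol[c] for c in C.CLASS_CODES])
        if np.all(np.abs(gap) <= tol_vec):
            converged = True
            break
        # proportional competition adjustment with oscillation damping
        flipped = (np.sign(gap) * np.sign(prev_gap)) < 0
        eta_vec[flipped] *= 0.7
        eta_vec[~flipped] = np.minimum(eta, eta_vec[~flipped] * 1.05)
        eta_vec = np.maximum(eta_vec, 1e-5)
        iter_vec += eta_vec * gap / np.maximum(demand_vec, 1.0)
        iter_vec = np.clip(iter_vec, -10.0, 10.0)
        prev_gap = gap

    allocated = {c: int((assign == c - 1).sum()) for c in C.CLASS_CODES}
    state = AllocationState(
        iterations=it,
        converged=converged,
        iter_offsets={c: float(iter_vec[c - 1]) for c in C.CLASS_CODES},
        allocated=allocated,
        demanded=demand,
    )
    if not converged:
        worst = max(C.CLASS_CODES, key=lambda c: abs(allocated[c] - demand[c]))
        raise AllocationError(
            f"allocation did not converge in {max_iter} iterations; worst class "
            f"{C.CLASS_NAMES[worst]}: allocated {allocated[worst]}, demanded {demand[worst]}"
        )
    out = current.copy()
    out.data[mask] = assign + 1
    return out, state


def simulate(
    base: LandUseGrid,
    trajectory,
    rules: TransitionRules,
    probabilities: dict[int, np.ndarray],
    tolerance: float = 0.005,
    max_iter: int = 2000,
    eta: float = 0.05,
    elas_mode: str = "incumbent",
) -> list[LandUseGrid]:
    """Run the yearly allocation over a demand trajectory.

    Returns the map sequence for every year after the base year; the
    location probabilities are static (the driving factors do not change
    within the simulation horizon).
    """
    grids, _ = simulate_with_states(
        base, trajectory, rules, probabilities,
        tolerance=tolerance, max_iter=max_iter, eta=eta, elas_mode=elas_mode,
    )
    return grids


def simulate_with_states(
    base: LandUseGrid,
    trajectory,
    rules: TransitionRules,
    probabilities: dict[int, np.ndarray],
    tolerance: float = 0.005,
    max_iter: int = 2000,
    eta: float = 0.05,
    elas_mode: str = "incumbent",
) -> tuple[list[LandUseGrid], list[AllocationState]]:
    """As :func:`simulate`, also returning per-year convergence diagnostics."""
    grids = [base]
    states: list[AllocationState] = []
    for year in trajectory.years[1:]:
        demand = trajectory.demand_cells(year)
        try:
            nxt, state = allocate_step(
                grids[-1], demand, rules, probabilities,
                tolerance=tolerance, max_iter=max_iter, eta=eta, elas_mode=elas_mode,
            )
        except (AllocationError, ValueError) as exc:
            raise AllocationError(f"year {year}: {exc}") from exc
        grids.append(nxt)
        states.append(state)
    return grids[1:], states
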