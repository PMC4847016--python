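"""Non-spatial demand module: land-use niches, ecosystem service values,
scenario linear programs, and yearly demand trajectories.

Decision variables (areas in hm²):

* ``x1..x8`` — horizon-year area of each land-use class *excluding*
  land reclaimed from abandoned mine land (AML);
* ``x9..x12`` — AML reclaimed to cultivated, garden, forest and
  construction land respectively.

The horizon-year demand of a class is its ``x`` plus any reclamation
variable feeding it.  Three scenarios are supported: ``planning``
(areas fixed by the general land-use plan — a trivially constrained
LP), ``niche`` (maximise the total land-use niche) and ``esv``
(maximise ecosystem service value with reclamation to construction
disallowed, x12 = 0).

Two well-documented quirks of the published constraint set are handled
explicitly: the suitability caps on x9..x12 sum to 3071.9 hm², 0.1 hm²
short of the 3072 hm² reclamation total, so the reclamation equality is
enforced as a narrow band [total − slack, total]; and under ``esv`` the
remaining caps cannot absorb the reclamation total, so the forest cap
is raised by the construction-suitable area (reclamation to forest has
laxer suitability criteria than to construction).  Both adjustments are
logged on the problem object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from . import constants as C
from .synthetic import largest_remainder

SCENARIOS = ("planning", "niche", "esv")

#: 0-based LP variable index of the reclamation variable feeding each class.
RECLAMATION_VAR = {C.CULTIVATED: 8, C.GARDEN: 9, C.FOREST: 10, C.CONSTRUCTION: 11}

VAR_NAMES = tuple(f"x{i}" for i in range(1, 13))

DEFAULT_NICHE_WEIGHTS = (0.4, 0.4, 0.2)


class InfeasibleLPError(ValueError):
    """The LP constraint set admits no feasible point."""


class UnboundedLPError(ValueError):
    """The LP objective is unbounded over the feasible set."""


def total_niche(nn: float, en: float, sn: float,
                weights: tuple[float, float, float] = DEFAULT_NICHE_WEIGHTS) -> float:
    """Total land-use niche: weighted sum of the natural, economic and
    social niche components (CNY·hm⁻²), default weights 0.4/0.4/0.2."""
    vals = (nn, en, sn)
    if not all(math.isfinite(v) and v >= 0 for v in vals):
        raise ValueError("niche components must be finite and non-negative")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("niche weights must sum to 1")
    return float(nn * weights[0] + en * weights[1] + sn * weights[2])


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the print convention of the source tables;
    float banker's rounding would mis-round exact halves)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def garden_esv(cultivated_esv: float, forest_esv: float) -> float:
    """Garden-land ESV proxy: midpoint of the cultivated- and forest-land
    ESVs, rounded to 2 decimals."""
    return round_half_up((float(cultivated_esv) + float(forest_esv)) / 2.0)


@dataclass
class NicheTable:
    """Per-class natural/economic/social/total niches (CNY·hm⁻²)."""

    table: pd.DataFrame
    weights: tuple[float, float, float] = DEFAULT_NICHE_WEIGHTS

    def __post_init__(self) -> None:
        t = self.table
        if "total" not in t.columns:
            t = t.assign(total=[
                total_niche(r.natural, r.economic, r.social, self.weights)
                for r in t.itertuples()
            ])
        for r in t.itertuples():
            expect = total_niche(r.natural, r.economic, r.social, self.weights)
            if abs(r.total - expect) > 1e-6:
                raise ValueError(f"total niche inconsistent for class {r.Index}")
        self.table = t

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "NicheTable":
        return cls(pd.read_csv(path, index_col="class_code"), **kw)

    @classmethod
    def default(cls) -> "NicheTable":
        with resources.files("minescape.data").joinpath("niche.csv").open() as fh:
            return cls(pd.read_csv(fh, index_col="class_code"))

    def total(self, code: int) -> float:
        return float(self.table.loc[code, "total"])


@dataclass
class ESVTable:
    """Per-class ecosystem service values (CNY·hm⁻²)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.table["esv"] < 0).any():
            raise ValueError("ESV must be non-negative")
        for code in (C.CONSTRUCTION, C.AML):
            if code in self.table.index and self.table.loc[code, "esv"] != 0:
                raise ValueError("construction land and AML must have zero ESV")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ESVTable":
        return cls(pd.read_csv(path, index_col="class_code"))

    @classmethod
    def default(cls) -> "ESVTable":
        with resources.files("minescape.data").joinpath("esv.csv").open() as fh:
            return cls(pd.read_csv(fh, index_col="class_code"))

    def value(self, code: int) -> float:
        return float(self.table.loc[code, "esv"])


def final_area_row(code: int) -> np.ndarray:
    """Coefficient row extracting a class's horizon-year area from x."""
    row = np.zeros(12)
    row[code - 1] = 1.0
    if code in RECLAMATION_VAR:
        row[RECLAMATION_VAR[code]] = 1.0
    return row


@dataclass
class LPProblem:
    """A scenario LP in max-c'x form with named constraints."""

    scenario: str
    c: np.ndarray
    A_ub: np.ndarray
    b_ub: np.ndarray
    ub_names: list[str]
    A_eq: np.ndarray
    b_eq: np.ndarray
    eq_names: list[str]
    bounds: list[tuple[float, float | None]]
    notes: list[str] = field(default_factory=list)

    @property
    def n_vars(self) -> int:
        return len(self.c)


@dataclass
class LPSolution:
    x: np.ndarray
    objective: float
    demands: dict[int, float]
    problem: LPProblem

    def as_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(VAR_NAMES, self.x)}


def build_lp(
    scenario: str,
    bounds: dict[int, float] | None = None,
    niches: NicheTable | None = None,
    esvs: ESVTable | None = None,
    extra_bounds: dict[int, tuple[float | None, float | None]] | None = None,
    plan_demand: dict[int, float] | None = None,
    total_area: float = C.TOTAL_AREA,
    reclamation_total: float = C.RECLAMATION_TOTAL,
    residual_aml: float = C.RESIDUAL_AML,
    plan_floors: dict[int, float] | None = None,
    include_x12_in_total: bool = True,
    reclamation_slack: float = 0.1,
    relax_forest_cap: bool = True,
    use_default_pins: bool = True,
) -> LPProblem:
    """Assemble the scenario LP.

    bounds are the suitability (MLS) caps on reclamation, keyed by
    destination class code.  extra_bounds are optional (low, high)
    bands on horizon-year class areas; when omitted under ``niche`` /
    ``esv``, shipped defaults pinning the classes the published
    constraint set leaves unbounded are applied (and noted).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    caps = dict(C.MLS_CAPS if bounds is None else bounds)
    if any(v < 0 for v in caps.values()):
        raise ValueError("suitability caps must be non-negative")
    floors = dict(C.PLAN_FLOORS if plan_floors is None else plan_floors)
    if any(v > total_area for v in floors.values()):
        raise ValueError("planning floors cannot exceed the total area")
    notes: list[str] = []

    niches = niches or NicheTable.default()
    esvs = esvs or ESVTable.default()
    if scenario == "esv":
        coeff = {code: esvs.value(code) for code in C.CLASS_CODES}
    else:
        coeff = {code: niches.total(code) for code in C.CLASS_CODES}
    c = np.zeros(12)
    for code in C.CLASS_CODES:
        c += coeff[code] * final_area_row(code)

    A_ub_rows, b_ub, ub_names = [], [], []
    A_eq_rows, b_eq, eq_names = [], [], []

    total_row = np.ones(12)
    if not include_x12_in_total:
        total_row[11] = 0.0
        notes.append("total-area equality uses the printed form without x12")
    A_eq_rows.append(total_row)
    b_eq.append(float(total_area))
    eq_names.append("total_area")

    recl_row = np.zeros(12)
    recl_row[8:12] = 1.0
    if reclamation_slack > 0:
        A_ub_rows.append(recl_row.copy())
        b_ub.append(float(reclamation_total))
        ub_names.append("reclamation_total_upper")
        A_ub_rows.append(-recl_row)
        b_ub.append(-(float(reclamation_total) - reclamation_slack))
        ub_names.append("reclamation_total_lower")
        notes.append(f"reclamation equality enforced as a {reclamation_slack} hm² band")
    else:
        A_eq_rows.append(recl_row)
        b_eq.append(float(reclamation_total))
        eq_names.append("reclamation_total")

    aml_row = np.zeros(12)
    aml_row[C.AML - 1] = 1.0
    A_eq_rows.append(aml_row)
    b_eq.append(float(residual_aml))
    eq_names.append("residual_aml")

    if scenario == "esv":
        if relax_forest_cap and C.CONSTRUCTION in caps:
            caps[C.FOREST] = caps.get(C.FOREST, 0.0) + caps[C.CONSTRUCTION]
            notes.append(
                "esv scenario: forest reclamation cap raised by the "
                f"construction-suitable area to {caps[C.FOREST]:.1f} hm²"
            )
        caps[C.CONSTRUCTION] = 0.0
    for code, var in RECLAMATION_VAR.items():
        if code in caps:
            row = np.zeros(12)
            row[var] = 1.0
            A_ub_rows.append(row)
            b_ub.append(float(caps[code]))
            ub_names.append(f"mls_cap_{C.CLASS_NAMES[code]}")

    for code, floor in floors.items():
        A_ub_rows.append(-final_area_row(code))
        b_ub.append(-float(floor))
        ub_names.append(f"plan_floor_{C.CLASS_NAMES[code]}")

    if scenario == "planning":
        demand = dict(C.PLANNING_DEMAND_2020 if plan_demand is None else plan_demand)
        for code in C.CLASS_CODES:
            if code == C.AML:
                continue  # already pinned by residual_aml
            A_eq_rows.append(final_area_row(code))
            b_eq.append(float(demand[code]))
            eq_names.append(f"plan_demand_{C.CLASS_NAMES[code]}")
        notes.append("planning scenario: demands fixed by the land-use plan")
    elif extra_bounds is None and use_default_pins:
        extra_bounds = {code: (v, v) for code, v in C.SCENARIO_PINS[scenario].items()}
        notes.append(
            "default per-class pins applied for classes the published "
            "constraint set leaves unbounded"
        )
    for code, (lo, hi) in (extra_bounds or {}).items():
        if lo is not None:
            A_ub_rows.append(-final_area_row(code))
            b_ub.append(-float(lo))
            ub_names.append(f"extra_floor_{C.CLASS_NAMES[code]}")
        if hi is not None:
            A_ub_rows.append(final_area_row(code))
            b_ub.append(float(hi))
            ub_names.append(f"extra_cap_{C.CLASS_NAMES[code]}")

    var_bounds: list[tuple[float, float | None]] = [(0.0, None)] * 12
    if scenario == "esv":
        var_bounds[11] = (0.0, 0.0)

    return LPProblem(
        scenario=scenario,
        c=c,
        A_ub=np.array(A_ub_rows),
        b_ub=np.array(b_ub),
        ub_names=ub_names,
        A_eq=np.array(A_eq_rows),
        b_eq=np.array(b_eq),
        eq_names=eq_names,
        bounds=var_bounds,
        notes=notes,
    )


def _diagnose_infeasible(problem: LPProblem) -> str:
    """Best-effort identification of the violated constraint by
    minimising elastic slack on each constraint family."""
    m_ub = len(problem.b_ub)
    m_eq = len(problem.b_eq)
    n = problem.n_vars
    # elastic program: minimise total slack
    A_ub = np.hstack([problem.A_ub, -np.eye(m_ub)]) if m_ub else np.empty((0, n + m_ub))
    A_eq_l = np.hstack([problem.A_eq, np.zeros((m_eq, m_ub)), -np.eye(m_eq), np.eye(m_eq)])
    cost = np.concatenate([np.zeros(n), np.ones(m_ub + 2 * m_eq)])
    bounds = list(problem.bounds) + [(0.0, None)] * (m_ub + 2 * m_eq)
    res = linprog(
        cost,
        A_ub=np.hstack([A_ub, np.zeros((m_ub, 2 * m_eq))]) if m_ub else None,
        b_ub=problem.b_ub if m_ub else None,
        A_eq=A_eq_l,
        b_eq=problem.b_eq,
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        return "infeasible (no single constraint identified)"
    slacks = res.x[n:]
    names = problem.ub_names + [f"{nm} (eq)" for nm in problem.eq_names] * 2
    worst = int(np.argmax(slacks))
    return f"constraint {names[worst % len(names)]!r} violated by {slacks[worst]:.4g} hm²"


def solve_lp(problem: LPProblem, feas_tol: float = 1e-6) -> LPSolution:
    """Solve the LP (HiGHS); certifies feasibility of the returned vertex
    constraint-by-constraint before reporting it."""
    res = linprog(
        -problem.c,
        A_ub=problem.A_ub if len(problem.b_ub) else None,
        b_ub=problem.b_ub if len(problem.b_ub) else None,
        A_eq=problem.A_eq if len(problem.b_eq) else None,
        b_eq=problem.b_eq if len(problem.b_eq) else None,
        bounds=problem.bounds,
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleLPError(
            f"scenario {problem.scenario!r} LP infeasible: {_diagnose_infeasible(problem)}"
        )
    if res.status == 3:
        raise UnboundedLPError(
            f"scenario {problem.scenario!r} LP unbounded; the objective-favoured "
            "class has no upper bound — supply extra_bounds"
        )
    if not res.success:
        raise RuntimeError(f"LP solver failed: {res.message}")
    x = res.x
    if len(problem.b_ub):
        viol = problem.A_ub @ x - problem.b_ub
        if viol.max() > feas_tol:
            i = int(np.argmax(viol))
            raise RuntimeError(f"solution violates {problem.ub_names[i]!r} by {viol.max():.3g}")
    if len(problem.b_eq):
        viol = np.abs(problem.A_eq @ x - problem.b_eq)
        if viol.max() > feas_tol:
            i = int(np.argmax(viol))
            raise RuntimeError(f"solution violates {problem.eq_names[i]!r} by {viol.max():.3g}")
    demands = {}
    if problem.n_vars == 12:  # scenario LPs; generic problems have no class mapping
        demands = {code: float(final_area_row(code) @ x) for code in C.CLASS_CODES}
    return LPSolution(x=x, objective=float(problem.c @ x), demands=demands, problem=problem)


def scenario_demand(scenario: str, **build_kw) -> tuple[dict[int, float], LPSolution]:
    """Horizon-year per-class demands for one scenario."""
    solution = solve_lp(build_lp(scenario, **build_kw))
    return solution.demands, solution


@dataclass
class DemandTrajectory:
    """Per-class target areas (hm²) for each yearly step."""

    areas: pd.DataFrame  # index: year, columns: class codes
    cell_area_hm2: float = 1.0

    def __post_init__(self) -> None:
        self.areas = self.areas.sort_index()
        self.areas.index.name = "year"

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.areas.index]

    @property
    def total_area(self) -> float:
        return float(self.areas.iloc[0].sum())

    def demand_cells(self, year: int) -> dict[int, int]:
        row = self.areas.loc[year]
        return {int(c): int(round(row[c] / self.cell_area_hm2)) for c in self.areas.columns}

    def to_csv(self, path: str | Path) -> None:
        out = self.areas.copy()
        out.columns = [C.CLASS_NAMES[int(c)] for c in out.columns]
        out.index.name = "year"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, cell_area_hm2: float = 1.0) -> "DemandTrajectory":
        df = pd.read_csv(path, index_col="year")
        df.columns = [C.NAME_TO_CODE[c] for c in df.columns]
        return cls(df, cell_area_hm2)


def interpolate_demand(
    base_areas: dict[int, float],
    target_areas: dict[int, float],
    base_year: int = C.BASE_YEAR,
    horizon_year: int = C.HORIZON_YEAR,
    cell_area_hm2: float = 1.0,
    total_slack: float = 0.5,
) -> DemandTrajectory:
    """Linear per-class interpolation from base to horizon areas, with
    each year's vector renormalised to whole cells summing to the
    landscape total by largest-remainder rounding."""
    codes = sorted(base_areas)
    if sorted(target_areas) != codes:
        raise ValueError("base and target areas must cover the same classes")
    base = np.array([float(base_areas[c]) for c in codes])
    target = np.array([float(target_areas[c]) for c in codes])
    if abs(base.sum() - target.sum()) > total_slack:
        raise ValueError(
            f"base ({base.sum():.4g}) and target ({target.sum():.4g}) totals "
            f"differ by more than {total_slack} hm²"
        )
    if horizon_year <= base_year:
        raise ValueError("horizon year must follow the base year")
    total_cells = int(round(base.sum() / cell_area_hm2))
    years = list(range(base_year, horizon_year + 1))
    n_steps = len(years) - 1
    rows = []
    for k, year in enumerate(years):
        frac = k / n_steps
        areas = base + (target - base) * frac
        cells = areas / cell_area_hm2
        if cells.sum() > total_cells:
            cells = cells * (total_cells / cells.sum())
        counts = largest_remainder(cells, total_cells)
        rows.append(counts * cell_area_hm2)
    df = pd.DataFrame(rows, index=years, columns=codes)
    return DemandTrajectory(df, cell_area_hm2)
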