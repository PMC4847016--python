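"""Mined-land suitability (MLS) assessment by the limit-condition method.

Each abandoned-mine-land patch is one assessment unit.  Seven limiting
factors (slope, surface material, soil organic matter, soil layer
thickness, irrigation/drainage, transport accessibility, land damage)
are graded 1/2/3/N for four candidate target uses (cultivated, garden,
forest, construction).  The unit grade is the grade of the most
limiting factor — the "cask principle": N (unsuitable) dominates
everything, and among numeric grades the largest class number (worst
quality) wins.  Per-use reclaimable-area bounds are the summed areas of
the suitable patches and feed the demand LP as caps.

Printed criteria with a grade range ("2 or 3", "3 or N") carry an
explicit resolution rule; the shipped default resolves to the worst
printed option (conservative for reclamation), selectable per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants as C

#: Unsuitable grade marker.
N = "N"

Grade = int | str  # 1 | 2 | 3 | "N"

FACTORS = (
    "slope_deg",
    "surface_material",
    "soil_organic_matter_pct",
    "soil_thickness_cm",
    "irrigation",
    "road_distance_m",
    "damage",
)

USES = ("cultivated", "garden", "forest", "construction")

#: Destination land-use class code for each target use.
USE_TO_CLASS = {
    "cultivated": C.CULTIVATED,
    "garden": C.GARDEN,
    "forest": C.FOREST,
    "construction": C.CONSTRUCTION,
}

_RANK = {1: 1, 2: 2, 3: 3, N: 4}


def _grade_rank(g: Grade) -> int:
    return _RANK[g]


def _parse_grade_token(tok: str) -> Grade:
    tok = tok.strip()
    return N if tok == N else int(tok)


@dataclass
class CriteriaTable:
    """Grading criteria: one row per (factor, value interval or category)
    with a grade entry per target use.

    Numeric intervals are half-open [low, high); "inf" marks an open
    upper end.  Grade entries may be ranges like "2|3" (ordered best to
    worst), resolved at lookup time.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(USES) - set(self.table.columns)
        if missing:
            raise ValueError(f"criteria table missing use columns: {sorted(missing)}")
        self._validate()

    def _validate(self) -> None:
        for factor, sub in self.table.groupby("factor"):
            kinds = sub["kind"].unique()
            if len(kinds) != 1:
                raise ValueError(f"mixed kinds for factor {factor}")
            if kinds[0] == "numeric":
                ivals = sorted((float(lo), float(hi)) for lo, hi in zip(sub["low"], sub["high"]))
                for (lo1, hi1), (lo2, _) in zip(ivals, ivals[1:]):
                    if lo2 < hi1:
                        raise ValueError(f"overlapping intervals for factor {factor}")
                    if lo2 > hi1:
                        raise ValueError(f"gap in intervals for factor {factor}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CriteriaTable":
        return cls(pd.read_csv(path, dtype={"category": str}))

    @classmethod
    def default(cls) -> "CriteriaTable":
        with resources.files("minescape.data").joinpath("criteria.csv").open() as fh:
            return cls(pd.read_csv(fh, dtype={"category": str}))

    def grade(self, factor: str, value, use: str, resolve: str = "worst") -> Grade:
        """Grade of the interval/category containing value, for one use."""
        if use not in USES:
            raise ValueError(f"unknown target use: {use}")
        if resolve not in ("worst", "best"):
            raise ValueError("resolve must be 'worst' or 'best'")
        sub = self.table[self.table["factor"] == factor]
        if sub.empty:
            raise ValueError(f"unknown factor: {factor}")
        kind = sub["kind"].iloc[0]
        if kind == "numeric":
            v = float(value)
            hit = sub[(sub["low"].astype(float) <= v) & (v < sub["high"].astype(float))]
        else:
            hit = sub[sub["category"] == str(value)]
        if hit.empty:
            raise ValueError(f"value {value!r} outside all intervals of factor {factor}")
        entry = str(hit[use].iloc[0])
        grades = [_parse_grade_token(t) for t in entry.split("|")]
        grades.sort(key=_grade_rank)
        return grades[-1] if resolve == "worst" else grades[0]


@dataclass
class SuitabilityResult:
    """Limit-condition assessment of one patch for every target use."""

    patch_id: int
    factor_grades: dict[str, dict[str, Grade]]  # use -> factor -> grade
    unit_class: dict[str, int | None]           # use -> 1|2|3 or None
    suitable: dict[str, bool]                   # use -> category

    def to_record(self) -> dict:
        rec = {"patch_id": self.patch_id}
        for use in USES:
            rec[f"{use}_class"] = self.unit_class[use] if self.suitable[use] else N
            rec[f"{use}_suitable"] = self.suitable[use]
        return rec


def grade_factor(value, factor: str, use: str,
                 criteria: CriteriaTable | None = None, resolve: str = "worst") -> Grade:
    """Grade one factor measurement for one target use."""
    criteria = criteria or CriteriaTable.default()
    return criteria.grade(factor, value, use, resolve=resolve)


def assess_patch(attrs: dict, criteria: CriteriaTable | None = None,
                 patch_id: int = 0, resolve: str = "worst") -> SuitabilityResult:
    """Assess one patch: for each use the unit grade is the most
    limiting factor grade; the unit is unsuitable iff any factor is N."""
    criteria = criteria or CriteriaTable.default()
    missing = [f for f in FACTORS if f not in attrs]
    if missing:
        raise ValueError(f"missing patch attributes: {missing}")
    factor_grades: dict[str, dict[str, Grade]] = {}
    unit_class: dict[str, int | None] = {}
    suitable: dict[str, bool] = {}
    for use in USES:
        grades = {f: criteria.grade(f, attrs[f], use, resolve=resolve) for f in FACTORS}
        factor_grades[use] = grades
        worst = max(grades.values(), key=_grade_rank)
        if worst == N:
            unit_class[use] = None
            suitable[use] = False
        else:
            unit_class[use] = int(worst)
            suitable[use] = True
    return SuitabilityResult(patch_id, factor_grades, unit_class, suitable)


def assess_patchset(patchset, criteria: CriteriaTable | None = None,
                    resolve: str = "worst") -> list[SuitabilityResult]:
    criteria = criteria or CriteriaTable.default()
    return [assess_patch(p.attrs, criteria, patch_id=p.id, resolve=resolve)
            for p in patchset]


def aggregate_bounds(results: list[SuitabilityResult],
                     patch_areas: list[float]) -> dict[str, float]:
    """Per-use reclaimable-area upper bounds: summed areas of the
    patches suitable for that use (hm²)."""
    if len(results) != len(patch_areas):
        raise ValueError("one area per assessment result required")
    bounds = {use: 0.0 for use in USES}
    for res, area in zip(results, patch_areas):
        for use in USES:
            if res.suitable[use]:
                bounds[use] += float(area)
    return bounds


def results_to_dataframe(results: list[SuitabilityResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_record() for r in results])
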