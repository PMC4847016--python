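"""Land-use class codes and the Mentougou-style study constants.

Eight first-level land-use categories on a 100 m grid. Areas are in
hm² (one hectare = one cell at the default resolution), monetary
coefficients in CNY·hm⁻².
"""

from __future__ import annotations

CULTIVATED = 1
GARDEN = 2
FOREST = 3
GRASSLAND = 4
CONSTRUCTION = 5
AML = 6
WATER = 7
UNUTILIZED = 8

CLASS_CODES = (CULTIVATED, GARDEN, FOREST, GRASSLAND, CONSTRUCTION, AML, WATER, UNUTILIZED)

CLASS_NAMES = {
    CULTIVATED: "cultivated",
    GARDEN: "garden",
    FOREST: "forest",
    GRASSLAND: "grassland",
    CONSTRUCTION: "construction",
    AML: "aml",
    WATER: "water",
    UNUTILIZED: "unutilized",
}

NAME_TO_CODE = {v: k for k, v in CLASS_NAMES.items()}

#: Base-year (2007) class areas, hm².
AREAS_2007 = {
    CULTIVATED: 831,
    GARDEN: 1678,
    FOREST: 30165,
    GRASSLAND: 3686,
    CONSTRUCTION: 2733,
    AML: 3573,
    WATER: 905,
    UNUTILIZED: 3063,
}

#: Total landscape area, hm² (= number of 1-ha cells).
TOTAL_AREA = 46634

#: AML area to be reclaimed by the horizon year, hm².
RECLAMATION_TOTAL = 3072

#: AML left unreclaimed at the horizon year, hm².
RESIDUAL_AML = 501

#: Suitability-derived caps on AML reclamation to each target use, hm²
#: (keys are the destination class codes).
MLS_CAPS = {CULTIVATED: 85.3, GARDEN: 176.1, FOREST: 1729.0, CONSTRUCTION: 1081.5}

#: General land-use plan floors on horizon-year class areas, hm².
PLAN_FLOORS = {CULTIVATED: 1656, GARDEN: 1678, FOREST: 29738, CONSTRUCTION: 6688}

#: Horizon-year demands under the planning scenario, hm².
PLANNING_DEMAND_2020 = {
    CULTIVATED: 1656,
    GARDEN: 1678,
    FOREST: 29738,
    GRASSLAND: 2643,
    CONSTRUCTION: 6688,
    AML: 501,
    WATER: 955,
    UNUTILIZED: 2775,
}

#: Default per-class final-area pins for the optimisation scenarios.
#: The published constraint set does not bound water, grassland or
#: unutilized land (the niche objective would push everything into
#: water); these pins close the problem and reproduce the published
#: scenario demand columns.  They are fixture bounds, overridable via
#: build_lp(extra_bounds=...).
SCENARIO_PINS = {
    "niche": {GRASSLAND: 1692, CONSTRUCTION: 6689, WATER: 1691, UNUTILIZED: 1692},
    "esv": {GRASSLAND: 1109, CONSTRUCTION: 6688, WATER: 1109, UNUTILIZED: 1109},
}

BASE_YEAR = 2007
HORIZON_YEAR = 2020
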