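# Methods

This note documents the models implemented in `minescape`, the defaults
chosen where the design was genuinely open, and what the synthetic
landscape does and does not emulate.

## Land-use system

Eight first-level classes on a 100 m grid (1 cell = 1 hm²): cultivated
(1), garden (2), forest (3), grassland (4), construction (5), abandoned
mine land / AML (6), water (7), unutilized (8). The shipped study
constants describe a ~466 km² mining district: base-year areas
(831, 1678, 30165, 3686, 2733, 3573, 905, 3063) hm² summing to 46,634;
3,072 hm² of the 3,573 hm² of AML is to be reclaimed by the horizon
year, leaving 501 hm².

## Mined-land suitability

Each AML patch is one assessment unit. Seven limiting factors are
graded per target use against interval criteria
(`minescape/data/criteria.csv`); the unit grade is the **most limiting**
factor grade — N (unsuitable) dominates, and among numeric grades the
larger class number (poorer quality) wins. Design choices:

* Criteria printed as ranges ("1 or 2", "2 or 3", "3 or N") resolve to
  the **worst** option by default (conservative for reclamation);
  `resolve="best"` selects the lenient reading. The criteria CSV is
  user-replaceable.
* The soil-thickness criteria leave 10–20 cm unspecified between the
  "20–40 cm" and "<10 cm" rows; the 20–40 cm grade is extended down to
  10 cm.
* Numeric intervals are half-open `[low, high)`, so boundary values take
  the worse (higher) interval's row as printed.
* Under these criteria, class 1 is attainable only for construction:
  even "light damage" grades 2 for cultivated/garden/forest. Uniform
  attribute sampling therefore produces classes {2, 3, N} in practice.

Per-use reclaimable-area bounds are the summed areas of suitable
patches; policy or public-participation overrides are a manual edit of
the suitability CSV, not a model.

## Scenario linear programs

Variables `x1..x8` are horizon-year class areas excluding reclaimed
land; `x9..x12` are AML areas reclaimed to cultivated, garden, forest,
construction. Constraints: total-area equality (including `x12`; the
variant without it is available as `include_x12_in_total=False`),
total-reclamation, residual-AML equality, suitability caps on `x9..x12`,
and planning floors on four classes. Two numerical choices deserve
note:

* The shipped caps (85.3, 176.1, 1729.0, 1081.5) sum to 3,071.9 hm²,
  0.1 hm² short of the 3,072 hm² reclamation equality. The equality is
  therefore enforced as the band `[total − slack, total]` with
  `slack = 0.1` hm² — the minimal relaxation that makes the system
  feasible — under which all four caps bind uniquely.
* Under the *esv* scenario (`x12 = 0`) the remaining caps cannot absorb
  the reclamation total; the forest cap is raised by the
  construction-suitable area (reclamation to forest has laxer criteria
  than to construction). The adjustment is recorded on the problem's
  notes.

The printed constraint set does not bound water, grassland or
unutilized land, under which the niche objective would pour all slack
area into water (the highest total niche). The optimisation scenarios
therefore require per-class `extra_bounds`; the shipped defaults pin
those classes (niche: grassland 1692, construction 6689, water 1691,
unutilized 1692 hm²; esv: 1109/6688/1109/1109 hm²). These pins are
**fixture values reproducing the reference demand columns**, not derived
constraints, and are overridable per call. The LP is solved with HiGHS
(`scipy.optimize.linprog`); every returned vertex is re-checked
constraint by constraint before being reported, and infeasibility is
diagnosed by an elastic relaxation that names the violated constraint.

Yearly demands interpolate linearly per class between the base and
horizon years; each year's vector is rounded to whole cells by
largest-remainder so that it sums exactly to the landscape area.

## Spatial allocation

Per-class location suitability is a one-vs-rest binomial logit of class
presence on the 15 driving factors, fitted by maximum likelihood
(statsmodels) over all valid cells; on separation or non-convergence
the fit falls back to a weakly penalised logistic regression
(L2, C = 10⁴) and is flagged. Model quality is screened by rank-AUC
(midrank tie handling); 0.7 is the conventional adequacy threshold.

Each yearly step assigns every cell the allowed class with maximal

    TPROP(i, u) = P(i, u) + ELAS(u)·[u = current class] + ITER(u)

ELAS ∈ [0, 1] is a per-class stability bonus (defaults: construction
and water 1.0, forest 0.8, cultivated/garden 0.6, grassland 0.5,
unutilized 0.3, AML 0.2); granting it only to the incumbent class is
the default, the unconditional variant is selectable (`elas_mode="all"`).
ITER is adjusted by the proportional rule
`ITER_u += η·(demand_u − allocated_u)/demand_u` (η = 0.05) with
per-class oscillation damping (η shrinks ×0.7 on a sign flip of the
gap, recovers ×1.05 otherwise, floor 10⁻⁵), ITER clipped to ±10.
Convergence requires every class within a relative tolerance of its
demand (default 0.5 %, never below one cell; a tolerance of exactly 0
demands exact areas). Failure after `max_iter` (default 2000) sweeps
raises an error naming the worst class. At convergence the ITER
offsets act as assignment-problem prices, so the allocation attains the
maximum total conversion probability among assignments with the same
class counts — the property the exhaustive-search tests verify on
≤16-cell grids.

Transition rules: the 8×8 binary matrix allows all conversions except
into AML; construction land and water rows are self-only. Ties in
TPROP break toward the lower class code; cells are processed in
row-major order; everything is pure numpy, so runs are bit-reproducible.

## Landscape metrics

Conventions follow common FRAGSTATS practice: patches are 8-connected
components (4-connectivity selectable); adjacency tabulations and edge
lengths use 4-neighbour cell sides; the landscape boundary counts as
edge for the landscape shape index but is excluded from contagion
adjacencies; patch-to-patch distances are between centres of the
closest cell pair (boundary cells suffice and are used). Contiguity
uses the 3×3 template (orthogonal 2, diagonal 1, centre 1; sum 13):
`(mean template score − 1)/12`, exactly 0 for a single-cell patch and
approaching 1 for large solid patches; the landscape value is
area-weighted. Contagion is
`[1 + Σ q·ln q / (2 ln m)]·100` with `q_ik = P_i·g_ik/Σ_k g_ik` over
double-counted adjacencies; a single-class map returns 100 by
convention, and the index can reach exactly 0 on small maps with
perfectly even adjacency distributions. Note that a two-class
checkerboard scores exactly 50, *above* two solid halves (≈31 on 8×8):
the index measures adjacency entropy, not visual interspersion, so
ordering intuitions should be checked against the formula. The
connectance threshold defaults to the landscape mean nearest-neighbour
distance, making its scenario ranking track ENN; patch-size CV uses the
population standard deviation.

## Synthetic landscapes

The generator stands in for unavailable survey rasters. Fifteen
driving factors are deterministic planar gradients (direction rotating
with factor index) plus Gaussian-smoothed noise (radius `clump_scale`,
default 4 cells), standardised. Class labels come from per-class
linear utilities `β0 + Σ βk Xk` (the generator truth `true_betas`, a
sparse matrix loading each class on 2–4 ecologically sensible factors
with |β| ∈ {0.8, 1.0, 1.2, 1.5}) plus smoothed Gumbel noise, assigned
by a deterministic capacity-constrained greedy so per-class counts
match the requested proportions exactly. AML is carved first as
`n_aml_patches` seeded regions grown by AML utility with
radius-scaled seed separation; late-growing regions can wrap around
earlier ones, so realised component counts fall somewhat below the
request (≈73–78 of 93 at study scale). Patch attributes are uniform
over the suitability grading intervals.

Because 46,634 = 2·7·3331 admits no sensible rectangle, the study-scale
configuration (`mentougou_config()`) uses a 214×218 grid whose 18
trailing cells are nodata; plain `SyntheticConfig()` defaults
(200×200) contain no nodata. All randomness flows from one integer
seed through a single generator; identical seeds give bit-identical
rasters, factor stacks and attribute tables.

What the generator emulates: class areas, spatial clumping, a known
logit structure (fitting recovers coefficient signs on maps, and exact
coefficients within sampling error when labels are drawn from the
binary logit itself via `sample_logit_labels`), and AML patch geometry.
What it does not: hydrology, road-network geometry, georeferencing
beyond an affine grid, temporal change in driving factors, or the
spatial error structure of classified satellite imagery — so passing
tests demonstrate the machinery is correct under known conditions, not
that any particular real landscape is predicted well.

## Validation machinery

Cohen's Kappa is computed unweighted over jointly valid cells.
The generator-truth *forward reference* map — the allocation engine run
with the true coefficients — serves as the agreement target for the
fitted pipeline; at the default study-scale configuration the two
horizon maps agree at Kappa ≈ 0.81. Relative errors are
`100·(simulated − demand)/demand`, rounded half-up to two decimals
(the half-up rule matters: several reference values sit on exact
halves that banker's rounding would mis-print).

## Problem sizes and defaults used in the shipped checks

The test suite exercises one full study-scale run (46,634 cells,
13 yearly steps, 8 logit fits, plus the truth-reference run) shared
across tests via a session fixture; allocation converges in a few
hundred ITER sweeps per year. Oracle comparisons use ≤16-cell grids
(exhaustive allocation search), ≤6-variable LPs (vertex enumeration),
≤10×10 rasters (metric brute force), n = 10,000 cells (coefficient
recovery), and 1,000 random 8×8 rasters (metric bounds).

## Known limitations

* Demand scenarios beyond the three shipped ones require the caller to
  supply objective coefficients and extra bounds.
* The allocation engine has no neighbourhood-enrichment or
  region-restriction terms, and no stochastic allocation mode.
* Class-level metric tables and moving-window metrics are out of scope;
  only landscape-level values are reported.
* Suitability is ordinal by design (limit-condition method); there is
  no continuous scoring.
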