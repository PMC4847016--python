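import itertools

import numpy as np
import pytest

from minescape import constants as C
from minescape.allocation import (
    AllocationError,
    TransitionRules,
    allocate_step,
    auc,
    default_transition_matrix,
    fit_logit,
    rank_auc,
    tprop,
)
from minescape.raster import DrivingFactorStack, LandUseGrid
from minescape.synthetic import (
    DEFAULT_TRUE_BETAS,
    SyntheticConfig,
    _generate_factors,
    sample_logit_labels,
)

# ------------------------------------------------------------------ rules


def test_default_rules_are_valid_and_violations_caught():
    TransitionRules()  # validates
    m = default_transition_matrix()
    m[C.CULTIVATED - 1, C.AML - 1] = 1  # conversion into AML
    with pytest.raises(ValueError, match="AML"):
        TransitionRules(matrix=m)
    m = default_transition_matrix()
    m[C.WATER - 1, C.FOREST - 1] = 1  # water losing cells
    with pytest.raises(ValueError, match="water"):
        TransitionRules(matrix=m)
    with pytest.raises(ValueError, match="ELAS"):
        TransitionRules(elas={C.FOREST: 1.5})


def test_tprop_is_additive_and_monotone_in_iter():
    assert tprop(0.3, 0.0, 0.0) == pytest.approx(0.3)
    assert tprop(0.3, 0.5, 0.1) == pytest.approx(0.9)
    p = np.array([0.2, 0.8])
    assert np.all(tprop(p, 0.1, 0.3) > tprop(p, 0.1, 0.1))


# ------------------------------------------------------------------ logits


def _two_class_grid(labels: np.ndarray, shape) -> LandUseGrid:
    return LandUseGrid(np.where(labels.reshape(shape) == 1, C.CULTIVATED, C.FOREST))


def test_separable_class_yields_perfect_auc():
    cfg = SyntheticConfig(n_rows=40, n_cols=40, seed=2)
    factors = _generate_factors(cfg, np.random.default_rng(2))
    labels = (factors.data[0] > 0).astype(int).ravel()
    grid = _two_class_grid(labels, (40, 40))
    model = fit_logit(grid, factors, C.CULTIVATED)
    assert model.regularized  # separation triggers the penalized fallback
    assert auc(model, grid, factors) == pytest.approx(1.0)


def test_independent_factors_give_chance_auc():
    cfg = SyntheticConfig(n_rows=100, n_cols=100, seed=3)
    factors = _generate_factors(cfg, np.random.default_rng(3))
    labels = np.random.default_rng(99).integers(0, 2, size=10_000)
    grid = _two_class_grid(labels, (100, 100))
    model = fit_logit(grid, factors, C.CULTIVATED)
    assert auc(model, grid, factors) == pytest.approx(0.5, abs=0.05)


def test_coefficients_recovered_within_three_standard_errors():
    """Labels drawn from the exact logit at n = 10,000: every fitted
    coefficient lies within 3 SE of the generating value."""
    cfg = SyntheticConfig(n_rows=100, n_cols=100, seed=7)
    factors = _generate_factors(cfg, np.random.default_rng(7))
    beta = DEFAULT_TRUE_BETAS[C.CULTIVATED - 1].copy()
    beta[0] = -1.0
    labels = sample_logit_labels(factors, beta, seed=11)
    grid = _two_class_grid(labels, (100, 100))
    model = fit_logit(grid, factors, C.CULTIVATED)
    assert not model.regularized
    z = np.abs(model.beta - beta) / model.bse
    assert z.max() < 3.0


def test_too_few_outcome_cells_rejected():
    grid = LandUseGrid(np.full((5, 5), C.FOREST))
    cfg = SyntheticConfig(n_rows=5, n_cols=5, n_aml_patches=1, seed=0)
    factors = _generate_factors(cfg, np.random.default_rng(0))
    with pytest.raises(ValueError, match="presence"):
        fit_logit(grid, factors, C.CULTIVATED)


def _pair_auc(labels, scores):
    """Brute-force AUC over all pairs: concordant + half of ties."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            conc += 1.0 if p > q else (0.5 if p == q else 0.0)
    return conc / total


@pytest.mark.parametrize("labels,scores", [
    ((0, 0, 1, 1), (0.1, 0.2, 0.8, 0.9)),   # perfectly ranked → 1.0
    ((0, 1, 0, 1), (0.4, 0.3, 0.2, 0.8)),   # mixed → 0.5 by pair counting
    ((0, 1, 0, 1), (0.5, 0.5, 0.5, 0.5)),   # all ties → 0.5
    ((0, 1, 1, 0, 1), (0.3, 0.3, 0.9, 0.1, 0.2)),
])
def test_auc_matches_pair_counting_oracle(labels, scores):
    assert rank_auc(np.array(labels), np.array(scores)) == pytest.approx(
        _pair_auc(labels, scores))


def test_auc_requires_both_labels():
    with pytest.raises(ValueError):
        rank_auc(np.array([1, 1, 1]), np.array([0.1, 0.2, 0.3]))


# ------------------------------------------------------------------ allocation


def _flat_probs(values: dict[int, np.ndarray]) -> dict[int, np.ndarray]:
    return {k: np.asarray(v, dtype=float).ravel() for k, v in values.items()}


def test_identity_rules_and_demand_return_the_input_map():
    data = np.array([[1, 3], [3, 4]])
    grid = LandUseGrid(data)
    rules = TransitionRules(matrix=np.eye(8, dtype=int))
    probs = _flat_probs({1: np.full(4, 0.2), 3: np.full(4, 0.2), 4: np.full(4, 0.2)})
    out, state = allocate_step(grid, {1: 1, 3: 2, 4: 1}, rules, probs, tolerance=0.0)
    assert np.array_equal(out.data, data)
    assert state.converged and state.iterations == 1


def _exhaustive_best(probs_a, probs_b, counts, incumbents, elas_a=0.0, elas_b=0.0):
    """Oracle: max total score over all assignments meeting the demand."""
    n = len(probs_a)
    best = -np.inf
    best_assign = None
    for combo in itertools.combinations(range(n), counts[0]):
        score = 0.0
        for i in range(n):
            if i in combo:
                score += probs_a[i] + (elas_a if incumbents[i] == 0 else 0.0)
            else:
                score += probs_b[i] + (elas_b if incumbents[i] == 1 else 0.0)
        if score > best:
            best = score
            best_assign = combo
    return best, best_assign


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_allocation_matches_exhaustive_search_on_small_grids(seed):
    """On ≤16-cell grids with exact demand, the converged allocation
    attains the exhaustive-search optimum of total conversion probability
    (the competition offsets act as prices for an assignment problem)."""
    rng = np.random.default_rng(seed)
    n = 16
    pa = rng.uniform(0.01, 0.99, n)
    pb = rng.uniform(0.01, 0.99, n)
    incumbents = rng.integers(0, 2, n)  # 0 → cultivated, 1 → forest
    data = np.where(incumbents.reshape(4, 4) == 0, C.CULTIVATED, C.FOREST)
    grid = LandUseGrid(data)
    elas = {c: 0.0 for c in C.CLASS_CODES}
    elas[C.CULTIVATED] = 0.15
    rules = TransitionRules(elas=elas)
    demand = {C.CULTIVATED: 8, C.FOREST: 8}
    probs = _flat_probs({C.CULTIVATED: pa, C.FOREST: pb})
    out, state = allocate_step(grid, demand, rules, probs, tolerance=0.0)
    counts = out.class_counts()
    assert counts == {C.CULTIVATED: 8, C.FOREST: 8}
    engine_score = sum(
        (pa[i] + (0.15 if incumbents.ravel()[i] == 0 else 0.0))
        if out.data.ravel()[i] == C.CULTIVATED else pb[i]
        for i in range(n)
    )
    oracle_score, _ = _exhaustive_best(pa, pb, (8, 8), incumbents.ravel(), elas_a=0.15)
    assert engine_score == pytest.approx(oracle_score, abs=1e-9)


def test_two_class_four_cell_toy_matches_oracle_assignment():
    pa = np.array([0.9, 0.8, 0.2, 0.1])
    pb = np.array([0.1, 0.3, 0.7, 0.95])
    grid = LandUseGrid(np.array([[1, 1], [3, 3]]))
    rules = TransitionRules(elas={c: 0.0 for c in C.CLASS_CODES})
    out, _ = allocate_step(grid, {1: 2, 3: 2}, rules,
                           _flat_probs({1: pa, 3: pb}), tolerance=0.0)
    assert np.array_equal(out.data, np.array([[1, 1], [3, 3]]))


def test_demand_must_sum_to_landscape_area():
    grid = LandUseGrid(np.array([[1, 3], [3, 3]]))
    rules = TransitionRules()
    with pytest.raises(ValueError, match="sum"):
        allocate_step(grid, {1: 1, 3: 2}, rules, _flat_probs({1: np.ones(4) * 0.5}))


def test_protected_class_demand_must_be_consistent():
    grid = LandUseGrid(np.full((3, 3), C.WATER))
    rules = TransitionRules()
    probs = _flat_probs({C.WATER: np.full(9, 0.5), C.FOREST: np.full(9, 0.5)})
    with pytest.raises(ValueError, match="convert away"):
        allocate_step(grid, {C.WATER: 5, C.FOREST: 4}, rules, probs)


def test_aml_demand_above_current_area_is_unsatisfiable():
    grid = LandUseGrid(np.array([[C.AML, C.FOREST], [C.FOREST, C.FOREST]]))
    rules = TransitionRules()
    probs = _flat_probs({C.AML: np.full(4, 0.5), C.FOREST: np.full(4, 0.5)})
    with pytest.raises(ValueError, match="convert into"):
        allocate_step(grid, {C.AML: 3, C.FOREST: 1}, rules, probs)


def test_nonconvergence_is_reported():
    grid = LandUseGrid(np.array([[1, 3], [3, 3]]))
    rules = TransitionRules(matrix=np.eye(8, dtype=int))
    probs = _flat_probs({1: np.full(4, 0.5), 3: np.full(4, 0.5)})
    # identity rules cannot move cells, so demand (3, 1) is unreachable
    with pytest.raises((AllocationError, ValueError)):
        allocate_step(grid, {1: 3, 3: 1}, rules, probs, tolerance=0.0, max_iter=50)


def test_allocation_is_deterministic(study_run):
    demand = study_run.trajectory.demand_cells(2008)
    a, _ = allocate_step(study_run.grid, demand, study_run.rules, study_run.probs)
    b, _ = allocate_step(study_run.grid, demand, study_run.rules, study_run.probs)
    assert np.array_equal(a.data, b.data)


# ------------------------------------------------- study-scale invariants


def test_yearly_maps_conserve_area(study_run):
    n = study_run.grid.n_valid
    for g in study_run.maps:
        assert g.n_valid == n
        assert sum(g.class_counts().values()) == n


def test_construction_and_water_are_irreversible(study_run):
    prev = study_run.grid
    for g in study_run.maps:
        for code in (C.CONSTRUCTION, C.WATER):
            before = prev.data == code
            after = g.data == code
            assert np.all(after[before]), C.CLASS_NAMES[code]
        prev = g


def test_aml_cell_set_never_grows(study_run):
    prev = study_run.grid
    for g in study_run.maps:
        assert not np.any((g.data == C.AML) & (prev.data != C.AML))
        prev = g


def test_every_year_meets_demand_within_tolerance(study_run):
    for year, g in zip(study_run.trajectory.years[1:], study_run.maps):
        demand = study_run.trajectory.demand_cells(year)
        counts = g.class_counts()
        for code, d in demand.items():
            tol = max(1, 0.005 * d)
            assert abs(counts.get(code, 0) - d) <= tol, (year, C.CLASS_NAMES[code])
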