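"""Shared fixtures.

The study-scale run (≈46,600 cells, 13 yearly steps) is expensive, so it
is built once per session and shared by the allocation-invariant,
evaluation and acceptance tests.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from minescape import allocation, constants as C, demand as demand_mod
from minescape.synthetic import forward_reference, generate_landscape, mentougou_config


@pytest.fixture(scope="session")
def study_run():
    """One seeded end-to-end study-scale run under the planning scenario:
    synthetic landscape, fitted logits, 13-year allocation, and the
    generator-truth reference map."""
    cfg = mentougou_config(seed=1)
    grid, factors, patchset = generate_landscape(cfg)
    models = allocation.fit_all_logits(grid, factors)
    probs = {c: m.predict(factors, grid.valid_mask) for c, m in models.items()}
    demands, _ = demand_mod.scenario_demand("planning")
    base_areas = {k: float(v) for k, v in grid.class_areas().items()}
    traj = demand_mod.interpolate_demand(base_areas, demands)
    rules = allocation.TransitionRules()
    maps, states = allocation.simulate_with_states(grid, traj, rules, probs)
    reference = forward_reference(cfg, rules, traj)
    return SimpleNamespace(
        config=cfg,
        grid=grid,
        factors=factors,
        patchset=patchset,
        models=models,
        probs=probs,
        trajectory=traj,
        rules=rules,
        maps=maps,
        states=states,
        final=maps[-1],
        reference=reference,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
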