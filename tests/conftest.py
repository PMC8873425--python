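"""Shared fixtures: one compact synthetic experiment run through both stages.

Session-scoped so the (seeded, deterministic) stage-1 and stage-2 fits are
computed once and reused by all modules that only inspect them.
"""

import numpy as np
import pytest

import phenocurve as pc


@pytest.fixture(scope="session")
def sim_small():
    cfg = pc.SimConfig(seed=11, n_times=10, missingness=0.03)
    table, truth = pc.simulate_experiment(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def spatial_spec_small():
    return pc.SpatialSpec(rows=10, cols=8, b_row=6, b_col=6)


@pytest.fixture(scope="session")
def series_small(sim_small, spatial_spec_small):
    _, table, _ = sim_small
    return pc.run_stage1(table, spatial_spec_small)


@pytest.fixture(scope="session")
def hfit_small(series_small):
    design = pc.build_hier_design(
        series_small, pc.HierConfig(b_pop=7, b_gen=7, b_plant=7))
    return pc.fit_growth(design)


@pytest.fixture(scope="session")
def grid_small(hfit_small):
    d = hfit_small.design
    return np.linspace(d.times[0], d.times[-1], 201)
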