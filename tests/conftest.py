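"""Shared fixtures: one small simulated trial reused across model tests."""

from __future__ import annotations

import numpy as np
import pytest

from heatqtl import simdata
from heatqtl.melmm import build_design
from heatqtl.types import FAParams, QTLSpec, SpatialParams


@pytest.fixture(scope="session")
def small_map():
    return simdata.simulate_linkage_map(2, 12, 100.0, seed=101)


@pytest.fixture(scope="session")
def small_pop(small_map):
    return simdata.simulate_dh_population(small_map, 60, seed=102)


@pytest.fixture(scope="session")
def small_trial(small_map, small_pop):
    """60 lines x 2 environments with FA G x E and AR1 x AR1 residuals."""
    envs = ["E1", "E2"]
    design = simdata.generate_prep_design(
        list(small_pop.lines), {2015: envs}, ["CHK1"], 2, grid_columns=6,
        seed=103)
    fa = FAParams(np.array([[0.5], [0.4]]), np.array([0.08, 0.1]))
    spatial = SpatialParams({e: (0.3, 0.3, 0.2) for e in envs})
    obs = simdata.simulate_phenotypes(
        design, small_pop, QTLSpec([]), {}, {"E1": 10.0, "E2": 12.0},
        fa, spatial, seed=104)
    spec = build_design(obs, design, dh_lines=small_pop.lines)
    return {"design": design, "obs": obs, "spec": spec, "fa": fa,
            "spatial": spatial, "geno": small_pop, "map": small_map}
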