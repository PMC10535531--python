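"""Shared fixtures.

The expensive emulated-study fixture (10,000 simulated waters, nine trained
retrieval networks and three attribution profiles) is session-scoped and
shared between the retrieval/attribution property tests and the acceptance
suite, so the full pipeline only runs once.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import cyanospec as cs

STUDY_SEED = 10609  # dataset seed for the emulated study
TRAIN_SEED = 11
ATTR_SEED = 12


@pytest.fixture(scope="session")
def grid():
    return cs.default_grid()


@pytest.fixture(scope="session")
def full_config(grid):
    """Decimated Full configuration: every 3rd of 300 channels, 12 nm FWHM."""
    full = cs.decimate(cs.srf_matrix(cs.cyanosat_centers(), 12.0, grid,
                                     name="300ch"), 3)
    return dataclasses.replace(full, name="Full")


@pytest.fixture(scope="session")
def small_rrs_dataset(grid):
    gen = dataclasses.replace(cs.GeneratorConfig(), data_types=("RRS",))
    return cs.generate_dataset(300, seed=123, config=gen, grid=grid)


@pytest.fixture(scope="session")
def emulated_run(grid, full_config):
    """Emulated study at n_waters = 10,000 (water-leaving reflectance only).

    For each product: Full/P1/P2 held-out metrics, the Full-model
    attribution profile, and the P1/P2 selections.
    """
    gen = dataclasses.replace(cs.GeneratorConfig(), data_types=("RRS",))
    dataset = cs.generate_dataset(10_000, seed=STUDY_SEED, config=gen, grid=grid)
    out = {}
    for product in cs.PRODUCTS:
        res = cs.evaluate(dataset, product, full_config, cs.TrainConfig(),
                          seed=TRAIN_SEED, run_cv=False)
        profile = cs.permutation_importance(
            res.model, res.X_test, res.y_test, full_config.centers,
            n_repeats=5, seed=ATTR_SEED, product=product, data_type="RRS")
        p1 = cs.select_p1(profile)
        p2 = cs.select_p2(profile)
        reports = {"Full": res.report}
        for sel in (p1, p2):
            # paired comparison: same training seed and data split as Full
            bc = cs.srf_matrix(np.asarray(sel.centers), 12.0, grid, name=sel.name)
            reports[sel.name] = cs.evaluate(dataset, product, bc,
                                            cs.TrainConfig(), seed=TRAIN_SEED,
                                            run_cv=False).report
        out[product] = {"reports": reports, "profile": profile,
                        "P1": p1, "P2": p2}
    return out
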