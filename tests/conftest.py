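"""Shared fixtures: synthetic molecules, bounds, restraints, small ensembles.

Everything is generated programmatically and seeded; the heavier ensembles are
session-scoped so several test modules can share one sampling run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from fcdg import dynamics, moltop, synthetic
from fcdg.synthetic import SyntheticSpec

warnings.filterwarnings("ignore", category=RuntimeWarning, module="fcdg")


@pytest.fixture(scope="session")
def rigid_fixture():
    return synthetic.make_fixture(SyntheticSpec(template="rigid", media=3, seed=3))


@pytest.fixture(scope="session")
def flexible_fixture():
    return synthetic.make_fixture(SyntheticSpec(template="flexible", media=1, seed=5))


@pytest.fixture(scope="session")
def rigid_bounds(rigid_fixture):
    return moltop.build_bounds(rigid_fixture.graph)


@pytest.fixture(scope="session")
def rigid_smoothed(rigid_bounds):
    return moltop.smooth_bounds(rigid_bounds)


@pytest.fixture(scope="session")
def holonomic_restraints(rigid_fixture):
    return synthetic.holonomic_restraints(rigid_fixture)


@pytest.fixture(scope="session")
def data_restraints(rigid_fixture):
    """Zero-noise 3-media RDCs + NOEs for the rigid fixture."""
    rs, tensors = synthetic.make_restraints(
        rigid_fixture, np.random.default_rng(7), k_rdc=1.0, k_noe=100.0,
        with_noe=True,
    )
    return rs, tensors


@pytest.fixture(scope="session")
def short_schedule():
    return dynamics.AnnealSchedule(time_step=5.0, hot_steps=120, cool_steps=180,
                                   t_hot=1.0)


@pytest.fixture(scope="session")
def prior_ensemble(rigid_fixture, rigid_bounds, holonomic_restraints, short_schedule):
    """Restraint-free (holonomic-only) ensemble of the rigid fixture, n=160."""
    return dynamics.run_ensemble(
        rigid_fixture.graph, rigid_bounds, holonomic_restraints,
        n_structures=160, schedule=short_schedule, seed=11,
        elements=rigid_fixture.elements, compression_steps=150,
        quench_cycles=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
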