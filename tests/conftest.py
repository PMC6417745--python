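"""Shared scenario fixtures.

The heavyweight meshes and transition matrices are built once per session
and shared across unit and acceptance tests.  Everything is generated
programmatically from a fixed seed; no data files are stored.
"""

import numpy as np
import pytest

import popmesh as pm
from popmesh.fixtures import make_fixture

SEED = 1


@pytest.fixture(scope="session")
def toy_fx():
    return make_fixture("toy_2strip", seed=SEED)


@pytest.fixture(scope="session")
def lattice_fx():
    return make_fixture("lattice_1d", seed=SEED, n_cells=50)


@pytest.fixture(scope="session")
def ring_fx():
    return make_fixture("ring_cycle", seed=SEED)


@pytest.fixture(scope="session")
def lif_fx():
    return make_fixture("lif_benchmark", seed=SEED)


@pytest.fixture(scope="session")
def qif_fx():
    return make_fixture("qif_grid", seed=SEED)


@pytest.fixture(scope="session")
def qif_gain_fx():
    """QIF grid at finer time step plus an inhibitory matrix for the
    balanced-input gain measurement."""
    fx = make_fixture("qif_grid", seed=SEED, h=0.05, dt=5e-5)
    fx["matrix_inh"] = pm.build_transition_matrix(
        fx["mesh"], (-0.05, 0.0), n_point=5000,
        seed=fx["streams"]["matrix"] + 7,
        threshold_v=fx["model"].threshold_v, locator=fx["locator"],
        mesh_id="qif",
    )
    return fx


@pytest.fixture(scope="session")
def eif_fx():
    return make_fixture("eif_1d", seed=SEED, dt=5e-5)


@pytest.fixture(scope="session")
def tm_fx():
    return make_fixture("tm", seed=SEED)


@pytest.fixture(scope="session")
def adexp_fx():
    return make_fixture("adexp", seed=SEED)


@pytest.fixture(scope="session")
def fhn_fx():
    return make_fixture("fhn", seed=SEED)


@pytest.fixture(scope="session")
def cond_runs():
    """Conductance-model steady-state runs with and without g_max.

    Returns {'free': (fixture, rates), 'gmax': (fixture, rates)}; the rate
    traces are shared by the firing-rate and transient-shape tests.
    """
    out = {}
    for key, gmax in (("gmax", 0.8), ("free", None)):
        fx = make_fixture("cond", seed=SEED, g_max=gmax)
        pop = pm.Population(fx["mesh"], fx["reversal"], fx["reset"], name="cond")
        res = pm.run(pop, [(fx["matrix"], 3000.0)], 0.6)
        out[key] = (fx, res.rate())
    return out


def population_of(fx, name="pop"):
    return pm.Population(
        fx["mesh"], fx.get("reversal"), fx.get("reset"), name=name
    )
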