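"""Shared fixtures.

The expensive fixture — a small-grid set of sustained chaotic states
of the Fenton-Karma model — is session-scoped and shared by the
experiment-level and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from lmpace import cell_models as cm
from lmpace import experiments as ex
from lmpace import tissue_sim as ts

FIXTURE_N = 144          # nodes per side of the reduced test grid
FIXTURE_D = 1.0          # cm^2/s; halved so the spiral wavelength fits
FIXTURE_SEED = 99


@pytest.fixture(scope="session")
def fk_model():
    return cm.get_model("FK")


@pytest.fixture(scope="session")
def fk_fixture_grid(fk_model):
    cfg = dict(ts.TABLE_GRIDS["FK"])
    return ts.SimGrid.from_units(N=FIXTURE_N, dx=cfg["dx"], dt=cfg["dt"],
                                 D_cm2_s=FIXTURE_D, Cm=cfg["Cm"])


@pytest.fixture(scope="session")
def fk_fixture_ics(fk_model, fk_fixture_grid):
    """Two screened chaotic states on the reduced grid."""
    rng = np.random.default_rng(FIXTURE_SEED)
    return ex.make_initial_conditions(
        fk_model, fk_fixture_grid, n_states=2, rng=rng, max_tries=12
    )


@pytest.fixture(scope="session")
def fixture_seed():
    return FIXTURE_SEED


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
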