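import numpy as np
import pytest

from fodm import (
    FixtureSpec, FodParams, HydroProfile, assign_hydrophobicity,
    effective_atoms, make_fixture, observed_profile, orient_unit, select,
    theoretical_profile,
)


@pytest.fixture(scope="session")
def ideal_model():
    model, bounds = make_fixture(FixtureSpec("ideal_micelle", 200, seed=1))
    return model, bounds


@pytest.fixture(scope="session")
def ideal_profiles(ideal_model):
    """(T, O) of the seed-1 ideal micelle, Gaussian spanning the unit."""
    model, _ = ideal_model
    records = assign_hydrophobicity(effective_atoms(model, select(model, "A")))
    oriented, env = orient_unit(records)
    return theoretical_profile(oriented, env), observed_profile(oriented)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_profile(n, rng, kind="O"):
    v = rng.random(n) + 1e-3
    return HydroProfile(kind, v / v.sum(), True)


@pytest.fixture
def default_params():
    return FodParams()
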