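"""Shared fixtures: generated molecule sets and one trained tiny model.

The overfit autoencoder is session-scoped because training it is the most
expensive step in the suite; the reconstruction test and the end-to-end
optimization tests all share the same trained instance.
"""

import numpy as np
import pytest

from molmoo.fixtures import FixtureSpec, generate_molecules


@pytest.fixture(scope="session")
def fixture_library() -> list[str]:
    return generate_molecules(FixtureSpec(n_molecules=300, seed=42))


@pytest.fixture(scope="session")
def small_library(fixture_library) -> list[str]:
    return fixture_library[:100]


@pytest.fixture(scope="session")
def overfit_result():
    from molmoo.presets import tiny_overfit_experiment
    return tiny_overfit_experiment(n_molecules=50, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
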