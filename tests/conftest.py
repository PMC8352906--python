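"""Shared fixtures: synthetic datasets at the study conditions.

The separable fixture is the default generator configuration (disjoint
exclusive zones, primary shared rate above secondary, 40 carcasses per
class); the negative control collapses the two classes onto one profile.
"""

import numpy as np
import pytest

from taphoseries import default_profiles, negative_control_profiles, simulate_dataset
from taphoseries.pipeline import split


@pytest.fixture(scope="session")
def separable_dataset():
    """40 samples/class, disjoint exclusive zones, seed 7."""
    return simulate_dataset(default_profiles(30, seed=7))


@pytest.fixture(scope="session")
def separable_split(separable_dataset):
    """Stratified 75/25 split of the separable fixture."""
    return split(separable_dataset, test_fraction=0.25, seed=7)


@pytest.fixture(scope="session")
def negative_control_dataset():
    """Distributionally identical classes (chance-level oracle)."""
    return simulate_dataset(negative_control_profiles(30, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
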