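import warnings

import numpy as np
import pytest

from bowtienet import worked_toy
from bowtienet.synthetic import (
    ExpansionModel,
    FanLaw,
    SyntheticSpec,
    generate_dataset,
)

# grid-searched SVR on heavy-tailed targets legitimately hits the
# iteration cap for some hyperparameter combinations
warnings.filterwarnings("ignore", message="Solver terminated early")


@pytest.fixture(scope="session")
def toy_pair():
    return worked_toy()


def small_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """A scaled-down study spec for fast tests."""
    defaults = dict(
        group_sizes={"r": 80, "b": 40, "g": 120},
        fan_law=FanLaw(n_mega=1, n_zero=2),
        expansion=ExpansionModel(),
        rng_seed=seed,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


@pytest.fixture(scope="session")
def small_pair_truth():
    return generate_dataset(small_spec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
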