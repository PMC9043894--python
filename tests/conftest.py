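import numpy as np
import pytest

from soildecay import reference
from soildecay.simulate import (
    Condition,
    DEFAULT_SCHEDULE,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def schedule():
    return DEFAULT_SCHEDULE.as_array()


@pytest.fixture(scope="session")
def gongzhuling_truths():
    return {
        Condition("Gongzhuling", t, w): p
        for (t, w), p in reference.PLATEAU_GONGZHULING.items()
    }


def simulate_condition(truth, *, condition=None, noise_cv=0.10,
                       noise_floor_sd=2.0, seed=0, replicates=3):
    """One-condition measurement table drawn from ``truth``."""
    condition = condition or Condition("Gongzhuling", 35.0, 20.0)
    cfg = SimulationConfig(
        truth={condition: truth},
        replicates=replicates,
        noise_cv=noise_cv,
        noise_floor_sd=noise_floor_sd,
        seed=seed,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_table():
    """Noise-free single-condition table from the 35 degC / 20% truth."""
    return simulate_condition(
        reference.PLATEAU_GONGZHULING[(35.0, 20.0)],
        noise_cv=0.0,
        noise_floor_sd=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
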