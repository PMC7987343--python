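import warnings

import pytest

from microstab.config import SimConfig
from microstab import simulate


@pytest.fixture(scope="session")
def default_design():
    return simulate.generate_design(SimConfig())


@pytest.fixture(scope="session")
def small_cfg():
    """A small gradient experiment: quick, but structurally complete."""
    return SimConfig(
        seed=101,
        n_taxa_fungi=30,
        n_taxa_bacteria=50,
        n_supporters_per_function_time=4,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    ds, effects = simulate.simulate_experiment(small_cfg)
    return ds, effects


@pytest.fixture(scope="session")
def balanced_cfg():
    """Uniform retention: taxon presence independent of treatment, so
    permutation effect sizes are unconfounded by the diversity gradient."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = SimConfig(
            seed=77,
            noise_sd=0.0,
            n_taxa_fungi=30,
            n_taxa_bacteria=50,
            n_supporters_per_function_time=3,
            p_negative=0.3,
            richness_retention=(0.6, 0.6, 0.6, 0.6),
        )
    return cfg


@pytest.fixture(scope="session")
def balanced_dataset(balanced_cfg):
    return simulate.simulate_experiment(balanced_cfg)
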