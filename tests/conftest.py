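import numpy as np
import pytest

from concordia import (
    CtSimConfig,
    SimulationConfig,
    generate_two_tissue_study,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A scaled-down study for fast unit tests (full size lives in acceptance)."""
    return SimulationConfig(
        n_genes=400,
        n_treatments=8,
        n_driver_treatments=2,
        module_size=40,
        n_samples_per_group_tissue1=8,
        n_samples_per_group_tissue2=8,
        n_annotation_terms=10,
        annotation_term_size=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return generate_two_tissue_study(small_cfg)


@pytest.fixture()
def noiseless_ct_cfg() -> CtSimConfig:
    return CtSimConfig(effect_a_dct=4.0, effect_b_dct=2.0, interaction_dct=1.5,
                       replicate_sd=0.0, n_replicates=3, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
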