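import numpy as np
import pytest

from glvnet import (
    GLVParameters,
    NoiseModel,
    SpeciesSet,
    generate_dataset,
    make_knockdown_design,
    preset_wt_network,
)
from glvnet.synth import DEFAULT_SPECIES


@pytest.fixture(scope="session")
def two_species_params() -> GLVParameters:
    """Small 2-species community with one true interspecies edge (B -> A)."""
    return GLVParameters(
        species=SpeciesSet(("A", "B")),
        growth_rates=np.array([0.6, 0.4]),
        interaction_matrix=np.array([[-6e-10, -1.5e-10], [0.0, -4e-10]]),
        indicator_matrix=np.array([[1, 1], [1, 1]]),
        process_noise_variances=np.array([1e12, 1e12]),
    )


@pytest.fixture(scope="session")
def wt_dataset():
    """One WT-preset knockdown dataset under process noise only."""
    params = preset_wt_network(0)
    design = make_knockdown_design(DEFAULT_SPECIES)
    data, record = generate_dataset(
        params, design, NoiseModel(measurement_cv=0.0), seed=0
    )
    return params, design, data, record
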