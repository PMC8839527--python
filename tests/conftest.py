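import pytest

from balticrrs import ModelCoefficients, PopulationParams, generate_dataset


@pytest.fixture(scope="session")
def baltic():
    return ModelCoefficients.baltic()


@pytest.fixture(scope="session")
def noiseless_table():
    """Station table generated exactly by the forward model (no noise)."""
    params = PopulationParams(n_stations=300, seed=11,
                              iop_noise_sigma_log10=0.0,
                              lu_noise_sigma_log10=0.0)
    return generate_dataset(params)


@pytest.fixture(scope="session")
def noisy_table():
    """Default-noise station table (IOP noise 0.14 dex)."""
    params = PopulationParams(n_stations=400, seed=23)
    return generate_dataset(params)
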