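import numpy as np
import pytest

from nitrite_chemostat import default_params
from nitrite_chemostat.regulatory import (
    NirExpressionParams,
    NrfExpressionParams,
    PotentialParams,
    TranslocationParams,
)


@pytest.fixture(scope="session")
def params():
    """The committed calibrated default parameter set."""
    return default_params()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


def random_nrf_params(rng) -> NrfExpressionParams:
    return NrfExpressionParams(
        delta_nrf_1=rng.uniform(0.0, 10.0),
        delta_nrf_2=rng.uniform(0.0, 10.0),
        K_nrf_1=rng.uniform(0.01, 5.0),
        K_nrf_2=rng.uniform(0.01, 5.0),
        h_nrf_1=rng.uniform(0.5, 8.0),
        h_nrf_2=rng.uniform(0.5, 8.0),
    )


def random_nir_params(rng) -> NirExpressionParams:
    return NirExpressionParams(
        delta_nir_1=rng.uniform(0.0, 10.0),
        delta_nir_2=rng.uniform(0.0, 50.0),
        K_nir_1=rng.uniform(0.01, 5.0),
        K_nir_2=rng.uniform(0.01, 5.0),
        h_nir_1=rng.uniform(0.5, 8.0),
        h_nir_2=rng.uniform(0.5, 8.0),
    )


def random_potential_params(rng) -> PotentialParams:
    return PotentialParams(
        K_pmf_1=rng.uniform(0.005, 1.0),
        K_pmf_2=rng.uniform(0.05, 2.0),
        K_pmf_3=rng.uniform(0.2, 3.0),
        h_pmf_1=rng.uniform(0.5, 6.0),
        h_pmf_2=rng.uniform(0.5, 6.0),
        h_pmf_3=rng.uniform(0.5, 12.0),
        delta_pmf=rng.uniform(0.0, 3.0),
        omega_1=rng.uniform(0.5, 50.0),
        omega_2=rng.uniform(0.0, 1.0),
    )


def random_transloc_params(rng) -> TranslocationParams:
    return TranslocationParams(
        kt_nrf_cp=rng.uniform(0.0, 0.2),
        kt_nrf_pc=rng.uniform(0.0, 0.2),
        d_U=rng.uniform(0.0, 20.0),
    )
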