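import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import trast as T

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tyr_rates() -> T.RateConstants:
    """Free-tyrosine rate constants (average fitted values)."""
    return T.RateConstants(k_ox=19.2e6, k_red=3.7e3)


@pytest.fixture
def two_state(tyr_rates) -> T.StateModel:
    """Two-state model at the peak excitation rate of 10.3 kW/cm²."""
    k01 = T.excitation_rate(tyr_rates.sigma, T.photon_flux(10.3, 280.0))
    return T.StateModel(
        topology="two_state",
        rates=tyr_rates,
        kox_eff=T.effective_kox(tyr_rates.k_ox, k01, tyr_rates.k10),
    )


@pytest.fixture
def beam() -> T.BeamProfile:
    return T.BeamProfile()


@pytest.fixture
def k01_peak(tyr_rates) -> float:
    return T.excitation_rate(tyr_rates.sigma, T.photon_flux(10.3, 280.0))


@pytest.fixture
def w_grid() -> np.ndarray:
    return T.default_w_grid()
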