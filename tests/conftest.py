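import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from metagrowth import (
    CohortScenario,
    GrowthParameters,
    LesionSeries,
    appendix_series,
    simulate_patient,
    volume_at,
)


@pytest.fixture(scope="session")
def appendix_params() -> GrowthParameters:
    """Parameters of the worked single-tumour Gompertz example."""
    return GrowthParameters(sgr0=0.001, lam=0.0003, v0=1.0, t0=0.0)


@pytest.fixture(scope="session")
def appendix_lesion() -> LesionSeries:
    """The worked example's 21 semiannual measurements as one series."""
    return appendix_series()


@pytest.fixture
def make_gompertz_series():
    """Factory: noiseless series sampled from an arbitrary growth curve."""

    def _make(params: GrowthParameters, times, lesion_id: str = "L") -> LesionSeries:
        times = np.asarray(times, dtype=float)
        return LesionSeries.from_arrays(lesion_id, times, volume_at(params, times))

    return _make


@pytest.fixture(scope="session")
def noiseless_gompertz_patient():
    """Default-scenario cohort with measurement noise switched off."""
    return simulate_patient(CohortScenario(noise_cv=0.0, seed=11))
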