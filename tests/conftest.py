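import numpy as np
import pytest

from qivive.pbpk import (
    ConcentrationTimeSeries,
    ExposureScenario,
    baseline_parameters,
)


@pytest.fixture(scope="session")
def baseline():
    return baseline_parameters()


@pytest.fixture(scope="session")
def oral_scenario():
    return ExposureScenario.oral(3.3, t_end=50.0)


def make_series(times, cv_maa, baseline, scenario):
    """Assemble a ConcentrationTimeSeries with a prescribed venous-blood MAA
    profile (all other states zero), for testing summary operations."""
    times = np.asarray(times, float)
    from qivive.pbpk import _STATE_NAMES
    states = {name: np.zeros_like(times) for name in _STATE_NAMES}
    states["c_vb2"] = np.asarray(cv_maa, float)
    return ConcentrationTimeSeries(times=times, states=states,
                                   parameters=baseline, scenario=scenario)


@pytest.fixture
def series_factory(baseline, oral_scenario):
    def _make(times, cv_maa):
        return make_series(times, cv_maa, baseline, oral_scenario)
    return _make
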