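import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qams import longan
from qams.chromdata import PeakRecord, PeakTable
from qams.synthetic import ExtractionSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def panel():
    return list(longan.PANEL)


@pytest.fixture
def uplc_curves():
    return {c: longan.calibration_curve("UPLC", c) for c in longan.COMPONENT_CODES}


@pytest.fixture
def hplc_curves():
    return {c: longan.calibration_curve("HPLC", c) for c in longan.COMPONENT_CODES}


@pytest.fixture
def extraction():
    return ExtractionSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_table():
    return PeakTable(records=[
        PeakRecord("s1", "UPLC", 6.2, 1500.0, 0.5, component_code="C1", injected_mass=0.049),
        PeakRecord("s1", "UPLC", 12.0, 8000.0, 0.5, component_code="C3"),
        PeakRecord("s2", "UPLC", 12.01, 4000.0, 0.5, injected_mass=None),
    ], provenance="fixture")
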