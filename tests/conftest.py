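import numpy as np
import pytest
from hypothesis import settings

from tserialed.geometry import BeamModel, DetectorGeometry, UnitCell

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def geom() -> DetectorGeometry:
    return DetectorGeometry(
        distance_mm=650.0, pixel_size_mm=0.1, n_fast=256, n_slow=256, beam_center=(128.0, 128.0)
    )


@pytest.fixture
def beam() -> BeamModel:
    return BeamModel(voltage_kv=200.0)


@pytest.fixture
def cubic_cell() -> UnitCell:
    return UnitCell(10.0, 10.0, 10.0, 90.0, 90.0, 90.0)


@pytest.fixture
def triclinic_cell() -> UnitCell:
    return UnitCell(11.1, 12.7, 14.4, 95.0, 98.5, 103.2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
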