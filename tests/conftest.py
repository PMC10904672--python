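import numpy as np
import pytest
from hypothesis import settings

from ctsim.config import (AcquisitionProtocol, FocalSpot, ScannerGeometry,
                          ScannerModel, SubsamplingScheme)
from ctsim.materials import EnergyGrid, build_material_db
from ctsim.synthetic import default_characterization

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def db120():
    return build_material_db(EnergyGrid.default(120.0))


@pytest.fixture(scope="session")
def desk_geometry():
    """Small axial geometry used throughout: 256-channel equiangular fan."""
    return ScannerGeometry(
        source_to_isocenter_mm=600.0, source_to_detector_mm=1100.0,
        n_channels=256, n_rows=1, channel_angular_pitch_rad=0.0012,
        row_pitch_mm=1.0, views_per_rotation=360, rotation_time_s=0.5,
        collimation_mm=1.0)


@pytest.fixture(scope="session")
def desk_model(desk_geometry):
    return ScannerModel(
        geometry=desk_geometry,
        focal_spots={"large": FocalSpot(1.4, 1.4, "large"),
                     "small": FocalSpot(0.7, 0.7, "small")},
        protocols={"body_120": AcquisitionProtocol(120.0, 200.0, 0.5,
                                                   "body", "large")},
        subsampling=SubsamplingScheme(1, 1, 1))


@pytest.fixture(scope="session")
def desk_char(desk_model):
    return default_characterization(desk_model)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
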