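import numpy as np
import pytest

from vheetps.base_data import AnalyticModelParams, BeamEnergySpec, generate_analytic_base_data
from vheetps.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def base200():
    return generate_analytic_base_data(BeamEnergySpec(200.0, 4.0))


@pytest.fixture(scope="session")
def base70():
    return generate_analytic_base_data(BeamEnergySpec(70.0, 4.0))


@pytest.fixture(scope="session")
def params():
    return AnalyticModelParams()


@pytest.fixture(scope="session")
def water_box_small():
    """40 mm water cube at 2 mm spacing with a centred 20 mm cuboid PTV."""
    return make_phantom(
        PhantomSpec("water_box", size_mm=(40.0, 40.0, 40.0), params={"ptv_half_size_mm": (10.0, 10.0, 10.0)})
    )


@pytest.fixture(scope="session")
def pelvis_small():
    """Reduced pelvis phantom (3 mm grid) for end-to-end tests."""
    return make_phantom(
        PhantomSpec(
            "pelvis",
            size_mm=(240.0, 180.0, 120.0),
            spacing_mm=(3.0, 3.0, 3.0),
            params={
                "body_half_axes_mm": (110.0, 80.0),
                "ptv_volume_cm3": 60.0,
                "ptv_half_axes_mm": (24.0, 24.0, 26.0),
                "rectum_radius_mm": 12.0,
                "bladder_radius_mm": 20.0,
            },
        )
    )


@pytest.fixture(scope="session")
def thorax_small():
    """Reduced midline thorax phantom (3 mm grid) for end-to-end tests."""
    return make_phantom(
        PhantomSpec(
            "thorax_midline",
            size_mm=(255.0, 159.0, 120.0),
            spacing_mm=(3.0, 3.0, 3.0),
            ptv_volume_cm3=80.0,
            params={
                "body_half_axes_mm": (120.0, 72.0),
                "ptv_half_axes_mm": (26.0, 26.0, 30.0),
            },
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
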