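import numpy as np
import pytest

import airwaymorph as am


@pytest.fixture(scope="session")
def coarse_airway_phantom():
    """Cylinder phantom at 0.8 mm voxels: cheap enough to share across tests."""
    spec = am.AirwayPhantomSpec(spacing=0.8)
    mask, lm, truth = am.make_airway_phantom(spec)
    return spec, mask, lm, truth


@pytest.fixture(scope="session")
def registration_phantom():
    return am.make_registration_phantom(spacing=0.8)


@pytest.fixture()
def aligned_head_landmarks():
    return am.LandmarkSet(points={
        "PoR": (-60.0, 0.0, 0.0), "PoL": (60.0, 0.0, 0.0),
        "OrR": (-30.0, 70.0, 0.0), "OrL": (30.0, 70.0, 0.0),
    })


@pytest.fixture()
def mandible_template():
    return dict(am.phantoms.DEFAULT_MANDIBLE_TEMPLATE)
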