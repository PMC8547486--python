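import numpy as np
import pytest

from hipmorph.hipgeom import LandmarkTemplate
from hipmorph.synthetic_hip import ShapeParams, generate_hip_outline


@pytest.fixture(scope="session")
def template() -> LandmarkTemplate:
    return LandmarkTemplate()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def clean_hip():
    """One noiseless cam hip with known ground truth (AA 72.5, LCEA 35, mJSW 4)."""
    params = ShapeParams(cam_present=True, cam_departure_deg=72.5)
    landmarks, truth = generate_hip_outline(params)
    return landmarks, truth, params
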