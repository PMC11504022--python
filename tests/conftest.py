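import numpy as np
import pytest

from cmbscreen.detector import DetectorConfig, build_detector
from cmbscreen.phantom import PhantomSpec, generate_patient


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(slices_per_patient=8, image_side=96, cmb_diameter=(4, 14))


@pytest.fixture(scope="session")
def positive_patient(small_spec):
    return generate_patient(small_spec, seed=42, force_positive=True)


@pytest.fixture(scope="session")
def tiny_detector_cfg():
    return DetectorConfig(scale="N", input_size=96, channels=(8, 16, 32, 64), depth=1,
                          score_threshold=0.25, seed=0)


@pytest.fixture(scope="session")
def tiny_detector(tiny_detector_cfg):
    return build_detector(tiny_detector_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
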