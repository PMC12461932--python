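import numpy as np
import pytest

from interphase import imaging, synthetic
from interphase.datatypes import CalibrationCurve

GAIN = 200.0  # intensity counts per g/L used throughout the image tests


@pytest.fixture(scope="session")
def calibration() -> CalibrationCurve:
    """Exact linear calibration recovered from noise-free standards."""
    standards, _ = synthetic.gen_calibration_standards(
        np.linspace(0.0, 2.0, 6), gain=GAIN, offset=0.0, noise_sd=0.0
    )
    return imaging.calibrate(standards)


@pytest.fixture(scope="session")
def clean_droplet():
    """Noise-free droplet image at the positively-charged-particle preset."""
    return synthetic.gen_droplet_image_preset("NP+", noise_model="none", gain=GAIN)
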