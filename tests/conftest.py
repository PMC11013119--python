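import numpy as np
import pytest

import nanofilm as nf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_level_image():
    """Noise-free two-level topography: 0 / 0.33 nm, 27% high phase."""
    values = np.zeros((64, 64))
    values[10:30, 12:40] = 0.33  # 560 px of 4096 ~ 13.7%
    values[40:60, 5:50] = 0.33   # + 900 px -> 35.6% total
    return nf.ScanImage(values, pixel_size=10.0, channel="topography")


@pytest.fixture
def small_truth():
    """Small disks-mode ground truth, big domains for quick profiling."""
    spec = nf.control_like_spec(shape=(256, 256), n_domains=10, seed=42)
    return nf.generate_mask(spec)
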