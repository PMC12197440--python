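import numpy as np
import pytest

from tlcdens.pipeline import PipelineConfig
from tlcdens.synthetic import build_assay_spec, render_plate


@pytest.fixture
def pipe_cfg():
    return PipelineConfig()


@pytest.fixture
def ladder_plate():
    """Noisy five-level standard ladder plate plus its manifest and lane table."""
    spec, lanes = build_assay_spec([0.5, 1, 2, 3, 4], noise_sd=0.005, seed=11)
    img, manifest = render_plate(spec)
    return img, manifest, lanes


@pytest.fixture
def rng():
    return np.random.default_rng(42)
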