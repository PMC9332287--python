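from dataclasses import replace

import numpy as np
import pytest

from atvseg import build_phantom, default_thorax_spec
from atvseg.phantom import NoiseSpec
from atvseg.pipeline import default_pipeline_denoiser


@pytest.fixture(scope="session")
def thorax_bundle():
    """Noiseless thorax-default phantom."""
    return build_phantom(default_thorax_spec())


@pytest.fixture(scope="session")
def noisy_bundle():
    """Thorax-default phantom with sigma=40 HU white noise, seed 1."""
    spec = replace(default_thorax_spec(), noise=NoiseSpec("white", 40.0), seed=1)
    return build_phantom(spec)


@pytest.fixture(scope="session")
def app_config():
    """The denoiser configuration the pipeline applies to whole CT slices."""
    return default_pipeline_denoiser()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
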