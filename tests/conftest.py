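import numpy as np
import pytest

from etquant.phantom import PhantomSpec, generate_phantom
from etquant.report import PipelineConfig, analyze_ear


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, no partial volume: binary-material phantom."""
    return PhantomSpec(seed=7, noise_sd=0.0, partial_volume=1)


@pytest.fixture(scope="session")
def clean_phantom(clean_spec):
    return generate_phantom(clean_spec)


@pytest.fixture(scope="session")
def clean_analysis(clean_spec):
    """Full pipeline run on the noise-free phantom."""
    return analyze_ear("clean", clean_spec, PipelineConfig(ears={"clean": clean_spec}))


@pytest.fixture(scope="session")
def noisy_analysis(default_spec):
    """Full pipeline run at the study noise/partial-volume conditions."""
    return analyze_ear("noisy", default_spec, PipelineConfig(ears={"noisy": default_spec}))


@pytest.fixture()
def rng():
    return np.random.default_rng(20230514)
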