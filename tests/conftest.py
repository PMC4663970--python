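import numpy as np
import pytest

from emdkit import (
    PhotoreceptorConfig,
    SynthImageParams,
    build_ensemble,
    make_kernels,
    synth_image_ensemble,
)


@pytest.fixture(scope="session")
def kernels():
    return make_kernels()


@pytest.fixture(scope="session")
def asym_images():
    """Light-dark-asymmetric synthetic panoramas (heavy tails, positive skew)."""
    params = SynthImageParams(spectral_slope=1.0, asymmetry=0.35, target_kurtosis=8.0, seed=101)
    return synth_image_ensemble(params, 120)


@pytest.fixture(scope="session")
def small_ensemble(asym_images):
    """400 mirror-paired clips: enough for quick fits, cheap to build."""
    return build_ensemble(asym_images, n_motions=200, seed=7)


@pytest.fixture(scope="session")
def study_ensemble(asym_images):
    """Desk-scale study ensemble: 10^4 mirror pairs over the asymmetric images."""
    return build_ensemble(asym_images, n_motions=10_000, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_banks(rng):
    """Random filtered-channel readouts (f1,g1,f2,g2,f3,g3) for identity checks."""
    return rng.standard_normal((1000, 6))


@pytest.fixture(scope="session")
def fast_cfg():
    """Short clips for tests that only exercise plumbing, not readout accuracy."""
    return PhotoreceptorConfig(duration=0.2)
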