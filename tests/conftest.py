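import warnings

import numpy as np
import pytest

import vcaseg

# The build-graph thinness warning is informational; keep test output clean.
warnings.filterwarnings("ignore", message="skeleton is not unit-width")


@pytest.fixture(scope="session")
def default_truth():
    """One synthetic angiogram at default (moderate-noise) conditions."""
    return vcaseg.generate(vcaseg.SynthParams(seed=7))


@pytest.fixture(scope="session")
def clean_truth():
    """Noise-free synthetic tree: no speckle, no clusters, no tails."""
    return vcaseg.generate(
        vcaseg.SynthParams(
            seed=11, speckle_sigma=0.0, n_noise_clusters=0, tail_artifact_strength=0.0
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
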