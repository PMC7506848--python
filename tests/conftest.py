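import numpy as np
import pytest

from nirchem import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic study: 120 samples, 3 origins, 511 bands."""
    data, truth = generate_dataset(SyntheticConfig(seed=7))
    return data, truth


@pytest.fixture(scope="session")
def clean_dataset():
    """Noiseless, scatter-free, class-offset-free spectra: absorbance is an
    exact affine function of lipid content."""
    cfg = SyntheticConfig(
        seed=3,
        noise_sd=0.0,
        scatter_sd=0.0,
        baseline_slope_sd=0.0,
        class_offsets={
            "Changbai": (0.0,) * 6,
            "Yichun": (0.0,) * 6,
            "Heihe": (0.0,) * 6,
        },
    )
    data, truth = generate_dataset(cfg)
    return data, truth
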