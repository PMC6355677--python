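import numpy as np
import pytest

from phenovol import synthetic_data as sd


@pytest.fixture(scope="session")
def wheat_small():
    """Noise-free scaled wheat bundle: 4 genotypes x {control, drought} x 3."""
    design, growth, wp = sd.wheat_ssd_preset(n_genotypes=4, cv_noise=0.0,
                                             factor_range=(0.6, 1.0))
    return sd.generate_experiment(design, growth, wp, seed=11)


@pytest.fixture(scope="session")
def tomato_bundle():
    """Full tomato biostimulant bundle with default noise."""
    return sd.generate_preset("tomato_rwm", seed=7)


@pytest.fixture(scope="session")
def tomato_noise_free():
    return sd.generate_preset("tomato_rwm", seed=7, cv_noise=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
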