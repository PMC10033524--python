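import numpy as np
import pytest

from bladderseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def noiseless_config():
    return PhantomConfig(noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_case(noiseless_config):
    """One noiseless phantom (volume, masks), shared across tests."""
    return generate_phantom(noiseless_config)


@pytest.fixture(scope="session")
def noisy_case():
    return generate_phantom(PhantomConfig(noise_sd=10.0, seed=3))


@pytest.fixture(scope="session")
def small_case(noiseless_case):
    """Noiseless phantom preprocessed to a desk-scale 32x32x8 grid."""
    from bladderseg.prep import preprocess_case

    volume, masks = noiseless_case
    return preprocess_case(volume, masks, target=(32, 32, 8))


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """A tiny on-disk phantom cohort (3 cases)."""
    from bladderseg.phantom import generate_cohort

    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(3, PhantomConfig(noise_sd=5.0), seed=11, out_dir=out)
    return out


def random_masks(rng, shape=(8, 8, 4), p=0.3):
    return (rng.random(shape) < p).astype(np.uint8)
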