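import pytest
from hypothesis import settings

from eqtm_kit import SimConfig, generate_dataset

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_dataset():
    """One desk-scale dataset at the default study conditions."""
    cfg = SimConfig(seed=1)
    m, expr, annotation, samples, truth = generate_dataset(cfg)
    return cfg, m, expr, annotation, samples, truth


@pytest.fixture(scope="session")
def clean_dataset():
    """Low-noise dataset with a well-specified two-factor latent space,
    used for parameter-recovery checks."""
    cfg = SimConfig(seed=7, n_latent=2, latent_sd=1.0, noise_sd_e=0.05)
    m, expr, annotation, samples, truth = generate_dataset(cfg)
    return cfg, m, expr, annotation, samples, truth
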