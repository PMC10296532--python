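import pytest
from hypothesis import settings

from estroscreen.synthetic_screen import GeneratorConfig, simulate_primary_screen

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Two-plate, two-line screen: fast but structurally complete."""
    return GeneratorConfig(n_library_plates=2, seed=42)


@pytest.fixture(scope="session")
def null_config() -> GeneratorConfig:
    """Noise-free screen with every compound effect programmed to 1.0."""
    return GeneratorConfig(
        n_library_plates=2,
        seed=7,
        well_noise_cv=0.0,
        toxic_fraction=0.0,
        hit_fraction=0.0,
        background_inhibition_mean=0.0,
        background_inhibition_sd=0.0,
    )


@pytest.fixture(scope="session")
def noise_free_config() -> GeneratorConfig:
    """Noise-free screen that keeps toxic compounds and hits."""
    return GeneratorConfig(n_library_plates=2, seed=11, well_noise_cv=0.0)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_primary_screen(small_config)


@pytest.fixture(scope="session")
def noise_free_dataset(noise_free_config):
    return simulate_primary_screen(noise_free_config)
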