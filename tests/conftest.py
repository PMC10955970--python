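import pytest

from holopol.io_core import FeatureSettings, OpticalConfig
from holopol.simulator import builtin_profiles


@pytest.fixture(scope="session")
def small_optics() -> OpticalConfig:
    """Desk-scale bench: 64x64 grid, no quantization, otherwise defaults."""
    return OpticalConfig(shape=(64, 64), bit_depth=None)


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


@pytest.fixture(scope="session")
def settings() -> FeatureSettings:
    return FeatureSettings()


@pytest.fixture(scope="session")
def tiny_table():
    """Small noiseless synthetic feature table shared by stats/classify tests.

    8 classes x 8 particles on 128x128 grids at z = 5 mm keeps every
    feature family non-degenerate while staying fast.
    """
    from holopol.pipeline import synthetic_feature_table

    return synthetic_feature_table(
        per_class=8,
        optics=OpticalConfig(shape=(128, 128), bit_depth=None),
        seed=99,
        noise=False,
    )
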