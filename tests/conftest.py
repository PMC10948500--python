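import numpy as np
import pytest

from itdeeg.synth import ClassProfile, SyntheticConfig, generate_epoch_set


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def small_config(**overrides) -> SyntheticConfig:
    """Reduced geometry for unit tests: fewer trials/channels, same rates."""
    defaults = dict(trials_per_class=12, n_channels=6, seed=7)
    defaults.update(overrides)
    if "profiles" not in defaults:
        centers = (8.0, 12.0, 16.0, 20.0, 24.0)
        subsets = ((0, 1), (1, 2), (2, 3), (3, 4), (4, 5))
        profiles = tuple(
            ClassProfile(c, 4.0, s, amplitude=0.3) for c, s in zip(centers, subsets)
        ) + (ClassProfile(0.0, 0.0, ()),)
        defaults["profiles"] = profiles
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_epochs():
    """72-trial, 6-channel discriminative set shared across tests."""
    return generate_epoch_set(small_config())
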