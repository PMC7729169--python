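import pytest

from nutrifuzz.asmod import TrainingConfig, train_all_outputs
from nutrifuzz.media import build_factor_table, load_ms_media, load_salt_registry
from nutrifuzz.simulate import OUTPUTS, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def registry():
    return load_salt_registry()


@pytest.fixture(scope="session")
def media(registry):
    return load_ms_media()


@pytest.fixture(scope="session")
def media_by_name(media):
    return {m.name: m for m in media}


@pytest.fixture(scope="session")
def design_table(registry, media):
    return build_factor_table(("BD", "BH", "BT"), media, [1, 2, 3, 4], registry)


@pytest.fixture(scope="session")
def synth():
    """Default synthetic dataset (seed 42, noise fraction 0.10) plus truth."""
    return generate_dataset(SimConfig(seed=42, noise_fraction=0.10))


@pytest.fixture(scope="session")
def trained(synth):
    """All six outputs trained on the default synthetic dataset."""
    table, truth = synth
    results = train_all_outputs(table, list(OUTPUTS), TrainingConfig(random_seed=42))
    return results, truth, table
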