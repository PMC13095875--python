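import dataclasses

import pytest

from rosawax import build_profiles, default_panel, generate


@pytest.fixture(scope="session")
def noise_free_panel():
    """The archetype panel with replicate noise switched off."""
    return [dataclasses.replace(s, noise_cv=0.0) for s in default_panel()]


@pytest.fixture(scope="session")
def noise_free_dataset(noise_free_panel):
    return generate(noise_free_panel, seed=20230901)


@pytest.fixture(scope="session")
def noise_free_profiles(noise_free_dataset):
    return build_profiles(
        noise_free_dataset.records, noise_free_dataset.metas
    )
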