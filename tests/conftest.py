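import pytest

from pmsckit import paper_regime_config, simulate_dataset


@pytest.fixture(scope="session")
def preset_dataset():
    """One shared paper-regime synthetic dataset (fixed seed)."""
    return simulate_dataset(paper_regime_config(seed=123))


@pytest.fixture(scope="session")
def preset_files(tmp_path_factory, preset_dataset):
    """The same dataset written to disk in the formats the readers consume."""
    from pmsckit.simulate import write_dataset

    out = tmp_path_factory.mktemp("preset")
    return write_dataset(preset_dataset, out)
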