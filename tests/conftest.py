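import pytest

from mirsites.synthetic import SyntheticConfig, generate_dataset, write_bundle

#: small but fully structured study used by integration-style tests
SMALL_CONFIG = SyntheticConfig(seed=7, n_genes=300, n_mirnas=80, n_samples=30, n_species=5)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_bundle(small_dataset, tmp_path_factory):
    """The small dataset written to disk, returned as its path manifest."""
    outdir = tmp_path_factory.mktemp("bundle")
    return write_bundle(small_dataset, outdir)
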