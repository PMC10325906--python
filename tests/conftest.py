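import pytest

from epiferro.synthdata import SimConfig, simulate_all


@pytest.fixture(scope="session")
def sim_config():
    """The generator's default study-design emulation, fixed seed."""
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def dataset(tmp_path_factory, sim_config):
    """One full synthetic dataset shared by the suite: (directory, truth)."""
    d = tmp_path_factory.mktemp("dataset")
    manifest = simulate_all(sim_config, d)
    return d, manifest
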