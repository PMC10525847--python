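import numpy as np
import pytest

from fundusroi.synthdata import SyntheticConfig, generate_dataset, load_manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 60-image synthetic dataset shared across tests (generated once)."""
    out = tmp_path_factory.mktemp("smalldata")
    config = SyntheticConfig(image_size=96, seed=7)
    manifest_path = generate_dataset(config, 60, out)
    return {
        "dir": out,
        "manifest_path": manifest_path,
        "manifest": load_manifest(manifest_path),
        "config": config,
    }
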