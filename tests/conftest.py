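import numpy as np
import pytest

from ctlabel.phantom import PhantomConfig, generate_dataset, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def phantom_volume():
    """One deterministic phantom scan (HU volume + ground-truth masks)."""
    return generate_phantom(PhantomConfig(n_slices=8, size=64, seed=7))


@pytest.fixture(scope="session")
def phantom_dataset(tmp_path_factory):
    """Four converted organ-present phantom scans in a PNG store."""
    out = tmp_path_factory.mktemp("phantom_store")
    manifests = generate_dataset(
        4, PhantomConfig(n_slices=16, size=64), seed=42, out_dir=out
    )
    return out, manifests
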