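import numpy as np
import pytest

from fedproto.synthetic import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_synth_cfg():
    """Desk-size generator settings for fast I/O tests."""
    return SynthConfig(
        n_exams=15, image_size=16, depth_range=(4, 9), seed=7,
        signal_strength=5.0, noise_sd=1.0,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_synth_cfg, tmp_path_factory):
    """A small MRNet-layout dataset written to disk once per session."""
    root = tmp_path_factory.mktemp("mrnet")
    ds = generate_dataset(tiny_synth_cfg, root)
    return root, ds
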