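import numpy as np
import pytest

import vsdikit as vk


@pytest.fixture(scope="session")
def geometry():
    """Default study field of view."""
    return vk.default_geometry()


@pytest.fixture(scope="session")
def tiny_geometry():
    """Small grid for fast unit tests: 4 x 3-row bands, 8-row margin."""
    bands = {label: (8 + 3 * i, 11 + 3 * i) for i, label in enumerate(vk.LAYER_LABELS)}
    return vk.build_geometry(20, 16, 33.3, 37.5, electrode_col=2,
                             layer_band_spec=bands, ca1_cols=(2, 14))


@pytest.fixture(scope="session")
def tiny_cfg():
    """Fast simulator configuration matched to the tiny geometry."""
    return vk.SimConfig(n_frames=128, stim_frame=8, sweep_noise="averaged")


@pytest.fixture(scope="session")
def quiet_cfg(tiny_cfg):
    """Noise-free variant of the fast configuration."""
    from dataclasses import replace

    return replace(tiny_cfg, noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160627)
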