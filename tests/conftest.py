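import numpy as np
import pytest
from hypothesis import settings

import mrisnn as m

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def sphere_cloud():
    return m.gen_head_cloud(1000, radius=85.0, seed=0)


@pytest.fixture(scope="session")
def case1_montage():
    return m.gen_montage_1020("case1")


@pytest.fixture(scope="session")
def small_layout(sphere_cloud, case1_montage):
    return m.place_neurons(sphere_cloud, case1_montage, 80,
                           frac_inhibitory=0.2, seed=42)


@pytest.fixture(scope="session")
def small_graph(small_layout):
    return m.build_neighborhoods(small_layout, 70.0)


@pytest.fixture(scope="session")
def synthetic_eeg():
    """Low-rank 15-channel fixture with spatially smooth source mixing."""
    mont = m.gen_montage_1020("case1")
    sources = np.array([[-50.0, 30.0, 40.0], [45.0, -40.0, 45.0]])
    mix = m.spatial_mixing(mont, sources)
    spec = m.SyntheticEEGSpec(n_channels=15, mixing=mix, seed=7,
                              channel_names=mont.names)
    sig, src, mixing = m.gen_synthetic_eeg(spec)
    return sig, src, mixing
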