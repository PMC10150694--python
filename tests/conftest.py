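"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

import frontcompete as fc


@pytest.fixture(scope="session")
def geometry():
    return fc.ChannelGeometry()


@pytest.fixture(scope="session")
def image_dataset():
    """Four image-tier events with moderate noise (session-cached)."""
    params = fc.GeneratorParams(n_events=4, seed=3, noise_sd=0.5)
    return fc.generate_dataset(params, tier="image")


@pytest.fixture(scope="session")
def one_movie(image_dataset):
    return image_dataset.events[0][0]


@pytest.fixture()
def disc_mask():
    rr, cc = np.mgrid[0:60, 0:60]
    return (rr - 30) ** 2 + (cc - 30) ** 2 <= 20 ** 2
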