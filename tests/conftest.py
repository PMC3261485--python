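import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import corddti as c
import corddti.tensorfit as tf

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

REGIONS = ("cervical", "thoracic", "lumbar")
DEFAULT_SHAPE = (64, 64, 28)


@pytest.fixture(scope="session")
def scheme():
    return c.make_gradient_scheme(20, 700.0)


@pytest.fixture(scope="session")
def phantoms():
    """Default-geometry phantom for each cord region, seed 1."""
    return {r: c.build_phantom(r, DEFAULT_SHAPE, seed=1) for r in REGIONS}


@pytest.fixture(scope="session")
def noisefree_maps(phantoms, scheme):
    """Noise-free scalar maps per region (exact forward model inversion)."""
    return {
        r: tf.fit_scalar_maps(c.simulate_dwi(ph, scheme, snr=np.inf))
        for r, ph in phantoms.items()
    }


def make_maps(md, fa):
    """Wrap bare (MD, FA) arrays in a ScalarMaps for clustering tests."""
    md = np.asarray(md, dtype=float)
    coords = np.column_stack([np.arange(len(md)), np.zeros(len(md), int), np.zeros(len(md), int)])
    return tf.ScalarMaps(
        coords=coords,
        fa=np.asarray(fa, dtype=float),
        md=md,
        shape=(len(md), 1, 1),
        voxel_size=(1.0, 1.0, 1.0),
    )
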