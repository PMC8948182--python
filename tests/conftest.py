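import numpy as np
import pytest

from stripekit.config import DetectionParams
from stripekit.contact_io import ContactMatrix, sqrt_vc_normalize
from stripekit.synthetic import (
    SyntheticMapSpec,
    StripeTruth,
    benchmark_scene,
    build_scene,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_symmetric(rng, n, scale=5.0):
    a = rng.random((n, n)) * scale
    return (a + a.T) / 2


@pytest.fixture
def random_matrix(rng):
    return ContactMatrix("chrT", 10_000, random_symmetric(rng, 40))


@pytest.fixture
def small_stripe_scene():
    """Noise-free 300-bin map with one planted 5' stripe (width 2, length 40)."""
    spec = SyntheticMapSpec(n_bins=300, resolution=10_000, noise="none", seed=1)
    truth = StripeTruth("5p", 100, 102, 40, 6.0, 1.0)
    m, stripes, loops = build_scene(spec, [truth])
    return m, truth


@pytest.fixture(scope="session")
def benchmark_run():
    """Full detection + scoring on the seed-fixed benchmark scene (shared)."""
    from stripekit.pipeline import call_stripes

    m, stripes, loops = benchmark_scene(seed=1)
    params = DetectionParams(seed=1)
    scored = call_stripes(m, params)
    return dict(matrix=m, normalized=sqrt_vc_normalize(m), params=params,
                stripes=stripes, loops=loops, scored=scored)
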