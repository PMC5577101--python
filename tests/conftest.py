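import numpy as np
import pytest

from ecmscreen import FibrilSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def clean_spec():
    """A sparse, noiseless, well-separated network: unambiguous branch recovery."""

    def make(seed: int) -> FibrilSpec:
        return FibrilSpec(
            n_major_fibres=3,
            n_mesh_fibres=3,
            major_width_px=2.0,
            mesh_width_px=1.5,
            noise_sigma=0.0,
            curvature=15.0,
            image_size=384,
            min_node_separation_px=40.0,
            seed=seed,
        )

    return make


@pytest.fixture
def field_arrays(rng):
    """Four random 64 x 64 uint16 field arrays sharing one well id."""
    return [rng.integers(0, 65535, (64, 64)).astype(np.uint16) for _ in range(4)]
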