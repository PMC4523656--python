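import numpy as np
import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # hypothesis is an optional test dependency
    pass

import tdcsim as t


@pytest.fixture(scope="session")
def small_head():
    """Reduced layered-sphere head (height-scaled, 4 mm voxels)."""
    params = t.AnthropometryParams.scaled_reference("small", 1.2, voxel_size=4.0)
    return t.build_layered_sphere_head(params)


@pytest.fixture(scope="session")
def small_head_case(small_head):
    """Symmetric montage A solved on the small head, normalised to 1 mA."""
    spec = t.standard_montage("A", electrode_scale=0.6)
    placed = t.place_montage(small_head, spec)
    return t.solve_montage(placed)


@pytest.fixture(scope="session")
def small_body():
    """Reduced whole-body phantom (adolescent-sized, 8 mm voxels)."""
    params = t.AnthropometryParams.scaled_reference("smallb", 1.47, voxel_size=8.0)
    return t.build_body_phantom(params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150721)
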