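import numpy as np
import pytest

from scatvam import (
    CameraSpec,
    GearSpec,
    ScatteringMedium,
    VialGeometry,
    make_gear,
    random_line_patterns,
    synthesize_sideview_stack,
)


@pytest.fixture(scope="session")
def small_gear():
    """Gear phantom at coarse-but-valid pitch for fast tests."""
    return make_gear(GearSpec(height=0.88), pitch=0.11)


@pytest.fixture(scope="session")
def vial16():
    return VialGeometry(16.0)


@pytest.fixture(scope="session")
def demo_medium():
    """The turbid-resin conditions used by the print demo."""
    return ScatteringMedium(l_s=6.1, sigma0=0.1, alpha=0.3, l_a=5.0)


@pytest.fixture(scope="session")
def characterized_stack():
    """Noiseless synthetic side-view stack of a known medium
    (100 random line patterns)."""
    medium = ScatteringMedium(l_s=5.0, sigma0=0.1, alpha=0.05)
    camera = CameraSpec(pixel_pitch=0.05, depth_pitch=0.1, n_depth=81)
    patterns = random_line_patterns(100, 256, np.random.default_rng(42))
    stack = synthesize_sideview_stack(patterns, medium, camera)
    return stack, medium
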