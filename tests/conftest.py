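import numpy as np
import pytest

from tfsearch import GeometryLayout, ModelConfig, StackSpec, build_geometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return ModelConfig()


@pytest.fixture
def small_geometry(default_config):
    """One 1000 bp segment with a centred TG in the standard nucleus."""
    layout = GeometryLayout(
        stacks=[StackSpec(n_segments=1, length_bp=1000)], tg=[(0, 500.0)])
    return build_geometry(default_config, layout)


@pytest.fixture
def stack_geometry():
    """Ten 420 bp segments with chain IST and a TG at the end of the top
    segment."""
    config = ModelConfig(ist_graph_kind="chain")
    layout = GeometryLayout(
        stacks=[StackSpec(n_segments=10, length_bp=420)], tg=[(9, 420.0)])
    return build_geometry(config, layout)
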