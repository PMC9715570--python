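import numpy as np
import pytest

from hiermotion.trees import ComponentSpec, MotionTree, shared_individual_tree


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def three_dot_tree():
    """1 shared + 3 individual components over 3 dots (2-D)."""
    return shared_individual_tree(3, n_dims=2)


@pytest.fixture()
def single_source_tree():
    """One individual component driving one input (D = 1)."""
    return MotionTree(
        [ComponentSpec("only", "translational", [1.0])],
        n_inputs=1, n_dims=1,
    )
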