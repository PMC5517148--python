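import pytest

from ephmap import GradientSpec, build_target_field

from helpers import make_terminal


@pytest.fixture
def uniform_ephrin_field():
    """20 x 8 field with homogeneous ephrin (L_T = 4), no EphA."""
    return build_target_field(
        20, 8,
        L_spec=GradientSpec(shape="uniform", level=4.0),
        R_spec=GradientSpec(shape="none"),
    )


@pytest.fixture
def zero_field():
    return build_target_field(
        20, 8, GradientSpec(shape="none"), GradientSpec(shape="none")
    )


@pytest.fixture
def counter_field():
    return build_target_field(
        50, 8,
        GradientSpec(shape="exponential_counter", rising=True, steepness=3.0),
        GradientSpec(shape="exponential_counter", rising=False, steepness=3.0),
    )


@pytest.fixture
def single_square_terminal():
    """Terminal whose disc covers exactly one unit square (weight 1)."""
    return make_terminal(x=10.5, y=4.5, radius=0.6)
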