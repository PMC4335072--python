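import pytest

from cellregen import Kernel, amputate, make_rectangle


@pytest.fixture
def poly2():
    return Kernel("polynomial", 2.0)


@pytest.fixture
def exp11():
    return Kernel("exponential", 11.0)


@pytest.fixture
def rect_12x8_cut4(poly2):
    """12x8 rectangle with the top 4 rows removed — the workhorse fixture."""
    rect = make_rectangle(12, 8)
    return amputate(rect, lambda n: n[1] >= 4)


@pytest.fixture
def square_3x3_cut_top(poly2):
    square = make_rectangle(3, 3)
    return amputate(square, lambda n: n[1] == 2)
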