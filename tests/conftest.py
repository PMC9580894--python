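import numpy as np
import pytest

from glyphstack.geometry import ClosedPath, make_shape
from glyphstack.template import bundled_templates


@pytest.fixture
def unit_square():
    """Unit square starting (0,0) -> (1,0) -> (1,1) -> (0,1)."""
    return ClosedPath(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def l_polygon():
    """Concave L: a 2x2 square with the top-right 1x1 quadrant notched out."""
    return ClosedPath(np.array([
        [0.0, 0.0], [2.0, 0.0], [2.0, 1.0], [1.0, 1.0], [1.0, 2.0], [0.0, 2.0]]))


@pytest.fixture
def circle_path():
    return make_shape("circle", r=1.0)


@pytest.fixture(params=["square", "rectangle", "circle", "ellipse", "lshape"])
def fixture_shape(request, l_polygon):
    """The portfolio of shapes the dense-sampling oracles run against."""
    return {
        "square": make_shape("square", side=2.0),
        "rectangle": make_shape("rectangle", width=3.0, height=1.5),
        "circle": make_shape("circle", r=1.2),
        "ellipse": make_shape("ellipse", rx=2.0, ry=0.8),
        "lshape": l_polygon,
    }[request.param]


@pytest.fixture(scope="session")
def templates():
    return bundled_templates()
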