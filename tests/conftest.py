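import numpy as np
import pytest

from platemorph.phantom import PhantomSpec, make_platelet_mask
from platemorph.types import BinaryMask


@pytest.fixture
def disk50():
    """Digitized disk of radius 50 px with its truth record."""
    mask, truth = make_platelet_mask(PhantomSpec(body_semi_axes=(50.0, 50.0)))
    return mask, truth


@pytest.fixture
def square60():
    """Axis-aligned 60x60 solid square, away from the border."""
    return BinaryMask(np.pad(np.ones((60, 60), dtype=bool), 5))


@pytest.fixture
def ellipse_30_15():
    mask, truth = make_platelet_mask(
        PhantomSpec(body_semi_axes=(30.0, 15.0), orientation=0.4)
    )
    return mask, truth
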