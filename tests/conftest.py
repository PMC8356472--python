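import numpy as np
import pytest

from corbound import CorMatrix

NA = np.nan

#: 4x4 worked-example matrix with the (2, 1)/(1, 2) correlation missing.
DEMO = np.array(
    [
        [1.0, NA, 0.5, 0.0],
        [NA, 1.0, 0.5, 0.3],
        [0.5, 0.5, 1.0, -0.1],
        [0.0, 0.3, -0.1, 1.0],
    ]
)

#: The same matrix after the two anchoring swaps (1,4) and (2,3): the missing
#: pair sits at (4, 3).
DEMO_SWAPPED = np.array(
    [
        [1.0, -0.1, 0.3, 0.0],
        [-0.1, 1.0, 0.5, 0.5],
        [0.3, 0.5, 1.0, NA],
        [0.0, 0.5, NA, 1.0],
    ]
)

#: Published feasible interval of the missing correlation of DEMO.
DEMO_LO = -0.4165129
DEMO_HI = 0.9518664


@pytest.fixture
def demo_matrix():
    return CorMatrix(DEMO)


@pytest.fixture
def swapped_demo():
    return CorMatrix(DEMO_SWAPPED)


def mask_pair(M: CorMatrix, i: int, j: int) -> CorMatrix:
    """Copy of M with the 1-based (i, j)/(j, i) pair set missing."""
    out = M.copy()
    out.values[i - 1, j - 1] = np.nan
    out.values[j - 1, i - 1] = np.nan
    return out
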