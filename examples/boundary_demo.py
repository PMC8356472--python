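"""Feasible bounds for one missing correlation.

Builds a 4-variable correlation matrix with the correlation between
variables 1 and 2 unreported, and asks: which values could that cell take
so that the completed matrix is still a valid (positive semidefinite)
correlation matrix?  The analytic solver answers via the correlative-angle
parameterization; the grid oracle confirms by brute force.
"""

import numpy as np

from corbound import CorMatrix, boundary_oracle, solve_boundary

NA = np.nan
demo = CorMatrix(
    [
        [1.0, NA, 0.5, 0.0],
        [NA, 1.0, 0.5, 0.3],
        [0.5, 0.5, 1.0, -0.1],
        [0.0, 0.3, -0.1, 1.0],
    ]
)

interval = solve_boundary(demo)
print(f"missing pair   : ({interval.anchor_row}, {interval.anchor_col})")
print(f"swaps to anchor: {list(interval.swaps)}")
print(f"feasible range : [{interval.lo:.7f}, {interval.hi:.7f}]")

oracle = boundary_oracle(demo, step=1e-4)
print(f"grid oracle    : [{oracle.lo:.7f}, {oracle.hi:.7f}]")

# The missing correlation can only lie between about -0.42 and 0.95: values
# outside break positive semidefiniteness given the observed correlations.
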