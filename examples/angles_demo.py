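"""The correlative-angle parameterization.

Every correlation matrix factors as R = L L' with unit-norm rows of L, so
each row can be written in spherical coordinates.  The resulting strictly
lower-triangular angle matrix maps [0, pi] entries back to valid matrices:
angle 0 at a position yields the largest correlation attainable there, pi
the smallest.  This is what turns the boundary problem into two conversions.
"""

import numpy as np

from corbound import CorMatrix, angle_to_cor, cor_to_angle

anchored = CorMatrix(
    [
        [1.0, -0.1, 0.3, 0.0],
        [-0.1, 1.0, 0.5, 0.5],
        [0.3, 0.5, 1.0, np.nan],
        [0.0, 0.5, np.nan, 1.0],
    ]
)

theta = cor_to_angle(anchored)
print("angle matrix (radians):")
print(np.round(theta.theta, 3))

for angle, label in [(0.0, "maximum"), (np.pi, "minimum")]:
    R = angle_to_cor(theta.with_anchor(angle))
    print(f"anchor angle {angle:.3f} -> correlation (4,3) = {R.values[3, 2]:.7f} ({label})")

# A complete round trip is exact: converting any valid matrix to angles and
# back reproduces it to floating-point precision.
from corbound import random_valid_matrix

R = random_valid_matrix(5, 42)
err = np.max(np.abs(angle_to_cor(cor_to_angle(R)).values - R.values))
print(f"round-trip error on a random valid 5x5 matrix: {err:.2e}")
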