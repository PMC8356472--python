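"""Correlative-angle (hypersphere) parameterization of correlation matrices.

Each row i of the Cholesky factor L of a correlation matrix R is a unit
vector, so it can be written in spherical coordinates with i-1 angles in
[0, pi]:

    L[i,1] = cos(theta[i,1])
    L[i,j] = cos(theta[i,j]) * prod_{k<j} sin(theta[i,k])   for 1 < j < i
    L[i,i] =                   prod_{k<i} sin(theta[i,k])

(1-based).  The strictly-lower-triangular matrix theta is the *correlative
angle matrix*: angle 0 at a position gives the largest correlation attainable
there, pi the smallest.  Any theta with entries in [0, pi] maps back to a
valid (PSD, unit-diagonal) correlation matrix, which is what makes the
parameterization useful both for bounding missing correlations and for
generating random valid matrices.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .corematrix import CorMatrix, cholesky_crout
from .errors import ValidityError

#: Slack allowed on an arccos argument before declaring an internal
#: inconsistency; arguments within the band are clamped to [-1, 1].
_ACOS_TOL = 1e-9

#: Below this, a running product of sines counts as zero: the remaining
#: correlations in the row are fully determined and their angles are set to 0
#: (any angle maps to the same matrix; 0 is the deterministic tie-break).
_SIN_PROD_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class AngleMatrix:
    """Strictly-lower-triangular matrix of angles in [0, pi] (radians).

    The diagonal and upper triangle are structurally zero.  The single entry
    at the anchor position (p, p-1) may be NaN when it parameterizes a
    missing correlation.
    """

    theta: np.ndarray

    @property
    def p(self) -> int:
        return self.theta.shape[0]

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.theta).any()

    def with_anchor(self, angle: float) -> "AngleMatrix":
        """Copy with the (p, p-1) anchor angle replaced."""
        t = self.theta.copy()
        t[-1, -2] = angle
        return AngleMatrix(t)


def cor_to_angle(M: CorMatrix) -> AngleMatrix:
    """Convert a correlation matrix to its correlative angle matrix.

    The input may be complete or missing exactly the symmetric pair at the
    anchor (p, p-1); in the latter case the anchor angle is NaN and every
    other angle is computed.

    Raises
    ------
    ValidityError
        If an implied cosine falls outside [-1, 1] by more than 1e-9
        (the factorization and the angle recursion disagree).
    """
    L = cholesky_crout(M)
    p = L.p
    theta = np.zeros((p, p))
    for i in range(1, p):
        sin_prod = 1.0
        for j in range(i):
            if L.undefined[i, j]:
                theta[i, j] = np.nan
                continue
            if sin_prod < _SIN_PROD_TOL:
                theta[i, j] = 0.0
                continue
            c = L.entries[i, j] / sin_prod
            if c > 1.0 + _ACOS_TOL or c < -1.0 - _ACOS_TOL:
                raise ValidityError(
                    f"internal inconsistency at angle position ({i + 1}, {j + 1}): "
                    f"implied cosine {c:.6g} outside [-1, 1]"
                )
            theta[i, j] = float(np.arccos(np.clip(c, -1.0, 1.0)))
            sin_prod *= float(np.sin(theta[i, j]))
    return AngleMatrix(theta)


def angle_to_cor(A: AngleMatrix) -> CorMatrix:
    """Convert a complete correlative angle matrix back to a correlation matrix.

    Builds the Cholesky rows from the spherical coordinates and returns
    L @ L.T, which is PSD with unit diagonal by construction.

    Raises
    ------
    ValidityError
        If any angle is missing or lies outside [0, pi] beyond 1e-12.
    """
    theta = A.theta
    p = A.p
    if np.isnan(theta).any():
        raise ValidityError("angle matrix has missing entries; set the anchor angle first")
    lower = np.tril(theta, k=-1)
    if (lower < -1e-12).any() or (lower > np.pi + 1e-12).any():
        bad = np.argwhere((lower < -1e-12) | (lower > np.pi + 1e-12))[0]
        raise ValidityError(
            f"angle at ({bad[0] + 1}, {bad[1] + 1}) outside [0, pi]: "
            f"{theta[bad[0], bad[1]]!r}"
        )
    L = np.zeros((p, p))
    L[0, 0] = 1.0
    for i in range(1, p):
        sin_prod = 1.0
        for j in range(i):
            t = min(max(theta[i, j], 0.0), np.pi)
            L[i, j] = np.cos(t) * sin_prod
            sin_prod *= np.sin(t)
        L[i, i] = sin_prod
    R = L @ L.T
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    np.clip(R, -1.0, 1.0, out=R)
    return CorMatrix(R, copy=False)


def random_valid_matrix(p: int, rng_seed: int | np.random.Generator) -> CorMatrix:
    """Generate a random valid correlation matrix for test fixtures.

    Each lower-triangle angle is drawn independently as ``arccos(U)`` with
    U ~ Uniform(-1, 1) — supported on the open interval (0, pi), so the
    resulting matrix is always strictly valid.  This gives a good spread of
    correlations but makes no claim of uniformity over the elliptope.

    Parameters
    ----------
    p
        Dimension, at least 2.
    rng_seed
        Integer seed or a numpy Generator.
    """
    if p < 2:
        raise ValidityError(f"matrix dimension must be at least 2, got {p}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    theta = np.zeros((p, p))
    idx = np.tril_indices(p, k=-1)
    theta[idx] = np.arccos(rng.uniform(-1.0, 1.0, size=len(idx[0])))
    return angle_to_cor(AngleMatrix(theta))
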