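"""Feasible bounds for a single missing correlation.

A missing correlation in an otherwise-valid correlation matrix cannot take
any value in [-1, 1]: positive semidefiniteness constrains it to a closed
interval (the *correlative interval*) determined by the observed entries.
The analytic solver moves the missing pair to the anchor position (p, p-1)
by symmetric row/column swaps, converts to the correlative angle matrix, and
sets the anchor angle to 0 (maximum) and pi (minimum) before converting
back.  A brute-force grid scanner over the eigenvalue condition is provided
as an independent check.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .angles import cor_to_angle
from .corematrix import PSD_TOL, CorMatrix
from .errors import DimensionError, InfeasibleError, MissingPatternError, ValidityError

#: All indices in this module's public API are 1-based (row, column).


@dataclasses.dataclass(frozen=True)
class BoundaryInterval:
    """Feasible range [lo, hi] for one missing correlation.

    ``anchor_row``/``anchor_col`` record the missing pair's lower-triangle
    position in the *original* (unswapped) matrix, 1-based; ``swaps`` lists
    the symmetric swaps that were applied to reach the anchor.
    """

    lo: float
    hi: float
    anchor_row: int
    anchor_col: int
    swaps: tuple[tuple[int, int], ...]

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def midpoint(self) -> float:
        return (self.lo + self.hi) / 2.0


def cor_swap(M: CorMatrix, i: int, j: int) -> CorMatrix:
    """Symmetric permutation: exchange rows i, j and columns i, j (1-based).

    Preserves the diagonal, the multiset of off-diagonal values (missing
    markers included) and the eigenvalues.
    """
    p = M.p
    for idx in (i, j):
        if not 1 <= idx <= p:
            raise DimensionError(f"swap index {idx} out of range 1..{p}")
    perm = np.arange(p)
    perm[i - 1], perm[j - 1] = perm[j - 1], perm[i - 1]
    return CorMatrix(M.values[np.ix_(perm, perm)], copy=False)


def locate_missing(M: CorMatrix) -> tuple[int, int]:
    """1-based lower-triangle position (i, j), i > j, of the single missing pair.

    Raises
    ------
    MissingPatternError
        If the matrix is complete ("nothing to solve") or has two or more
        missing pairs (use sequential imputation for those).
    """
    pairs = M.missing_pairs()
    if not pairs:
        raise MissingPatternError("matrix is complete: nothing to solve")
    if len(pairs) > 1:
        raise MissingPatternError(
            f"{len(pairs)} missing pairs at {pairs}: the boundary solver handles "
            "exactly one; impute sequentially for multiple missing correlations"
        )
    return pairs[0]


def move_missing_to_anchor(M: CorMatrix) -> tuple[CorMatrix, tuple[tuple[int, int], ...]]:
    """Permute the matrix so its single missing pair sits at (p, p-1).

    At most two symmetric swaps are ever needed.  The swap sequence is
    deterministic: with the missing pair at (i, j), i > j, either index that
    already sits in {p-1, p} is left alone and the other is swapped in;
    otherwise j is swapped with p and then i with p-1.  Returns the permuted
    matrix and the swaps applied (in order), enabling exact inversion.
    """
    i, j = locate_missing(M)
    p = M.p
    swaps: list[tuple[int, int]] = []
    if (i, j) == (p, p - 1):
        pass
    elif i == p:  # j < p-1: bring j to p-1
        swaps.append((j, p - 1))
    elif i == p - 1:  # j < p-1: bring j to p, p-1 already occupied
        swaps.append((j, p))
    else:  # both below p-1: two swaps, mirroring the worked two-swap recipe
        swaps.append((j, p))
        swaps.append((i, p - 1))
    out = M
    for a, b in swaps:
        out = cor_swap(out, a, b)
    return out, tuple(swaps)


def solve_boundary(M: CorMatrix, psd_tol: float = PSD_TOL) -> BoundaryInterval:
    """Analytic feasible interval for the single missing correlation.

    After anchoring, the angle matrix is computed; setting the anchor angle
    to 0 and back-converting gives the maximum feasible correlation, pi the
    minimum.  When the observed entries leave no freedom (a zero sine
    product), lo == hi: a single feasible value, not an error.

    Raises
    ------
    ValidityError
        If the observed part of the matrix is itself not PSD.
    """
    anchored, swaps = move_missing_to_anchor(M)
    i, j = locate_missing(M)
    p = M.p
    sub = anchored.values[: p - 1, : p - 1]
    sub_min = float(np.linalg.eigvalsh((sub + sub.T) / 2.0)[0])
    if sub_min < -psd_tol:
        raise ValidityError(
            f"observed submatrix is not positive semidefinite "
            f"(min eigenvalue {sub_min:.3e}); no feasible completion exists"
        )
    theta = cor_to_angle(anchored)
    hi = angle_to_cor_anchor(theta, 0.0)
    lo = angle_to_cor_anchor(theta, np.pi)
    if lo > hi:  # numerically possible only in degenerate zero-width cases
        lo, hi = hi, lo
    return BoundaryInterval(lo=lo, hi=hi, anchor_row=i, anchor_col=j, swaps=swaps)


def angle_to_cor_anchor(theta, angle: float) -> float:
    """Entry (p, p-1) of the matrix obtained by fixing the anchor angle."""
    from .angles import angle_to_cor

    completed = angle_to_cor(theta.with_anchor(angle))
    return float(completed.values[-1, -2])


def boundary_oracle(
    M: CorMatrix, step: float = 1e-4, psd_tol: float = PSD_TOL
) -> BoundaryInterval:
    """Brute-force check of :func:`solve_boundary` by eigenvalue grid scan.

    Substitutes every candidate value in -1..1 (increments of ``step``) into
    the missing pair and keeps those whose completed matrix has minimum
    eigenvalue >= -psd_tol.  Independent of the swap/angle machinery: no
    permutation, no Cholesky.
    """
    if step <= 0:
        raise ValidityError(f"step must be positive, got {step}")
    i, j = locate_missing(M)
    base = M.values.copy()
    base[i - 1, j - 1] = 0.0
    base[j - 1, i - 1] = 0.0
    E = np.zeros_like(base)
    E[i - 1, j - 1] = 1.0
    E[j - 1, i - 1] = 1.0
    candidates = np.arange(-1.0, 1.0 + step / 2.0, step)
    stack = base[None, :, :] + candidates[:, None, None] * E[None, :, :]
    min_eigs = np.linalg.eigvalsh(stack)[:, 0]
    feasible = candidates[min_eigs >= -psd_tol]
    if feasible.size == 0:
        raise InfeasibleError(
            "no candidate value yields a PSD completion: the observed part of "
            "the matrix is not a valid correlation matrix"
        )
    return BoundaryInterval(
        lo=float(feasible.min()),
        hi=float(feasible.max()),
        anchor_row=i,
        anchor_col=j,
        swaps=(),
    )
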