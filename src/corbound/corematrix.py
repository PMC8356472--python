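"""Correlation-matrix container, validity checking and the Cholesky-Crout factorization.

A correlation matrix here is a square symmetric matrix with unit diagonal and
off-diagonal entries in [-1, 1]; cells may be *missing* (stored as NaN, always
in symmetric pairs).  A complete matrix is additionally *valid* when it is
positive semidefinite.  The Cholesky-Crout routine factors a valid matrix R
into a lower-triangular L with L @ L.T == R, proceeding column by column from
the upper-left corner; it tolerates a single missing pair at the *anchor*
position (p, p-1), in which case the two entries of L that depend on the
missing cell are left undefined and flagged.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DecompositionError,
    DimensionError,
    MissingPatternError,
    ValidityError,
)

#: Eigenvalues >= -PSD_TOL count as positive semidefinite.  Semidefinite
#: boundary matrices arise by construction at interval endpoints, so an exact
#: zero cutoff would misclassify them under floating-point noise.
PSD_TOL = 1e-8

#: Tolerance for the diagonal radicand in the Cholesky-Crout recursion.  A
#: radicand in (-CHOL_TOL, CHOL_TOL] is clamped to zero (semidefinite pivot);
#: anything below -CHOL_TOL is a genuine PSD violation.
CHOL_TOL = 1e-12

#: Default token for missing cells in delimited files, matching R's display.
NA_TOKEN = "NA"


class CorMatrix:
    """A p x p correlation matrix whose cells may be missing.

    Parameters
    ----------
    values
        Square array-like; missing cells are NaN.  The diagonal must be
        complete; structural validity (unit diagonal, symmetry, range, PSD)
        is checked by :func:`validate`, not by the constructor.
    copy
        Copy the input array (default) or adopt it.
    """

    __slots__ = ("values",)

    def __init__(self, values, *, copy: bool = True):
        arr = np.array(values, dtype=float, copy=copy)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            shape = arr.shape if arr.ndim == 2 else (arr.ndim, "d")
            raise DimensionError(
                f"correlation matrix must be square, got shape {arr.shape}"
                if arr.ndim == 2
                else f"correlation matrix must be 2-dimensional, got {arr.ndim} dimensions"
            )
        if arr.shape[0] < 2:
            raise DimensionError(f"correlation matrix must be at least 2x2, got {arr.shape}")
        self.values = arr

    # -- basic introspection -------------------------------------------------

    @property
    def p(self) -> int:
        """Matrix dimension."""
        return self.values.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean p x p mask, True where a cell is missing."""
        return np.isnan(self.values)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def missing_pairs(self) -> list[tuple[int, int]]:
        """1-based lower-triangle positions (i, j), i > j, of missing pairs."""
        mask = self.missing_mask
        rows, cols = np.nonzero(np.tril(mask, k=-1))
        return [(int(r) + 1, int(c) + 1) for r, c in zip(rows, cols)]

    def copy(self) -> "CorMatrix":
        return CorMatrix(self.values, copy=True)

    @classmethod
    def identity(cls, p: int) -> "CorMatrix":
        return cls(np.eye(p), copy=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CorMatrix(p={self.p}, n_missing_pairs={len(self.missing_pairs())})"


@dataclasses.dataclass(frozen=True)
class ValidityReport:
    """Outcome of the four correlation-matrix validity conditions.

    ``psd`` is None (indeterminate) when missing entries prevent an
    eigenvalue check; likewise ``min_eigenvalue``.
    """

    is_square: bool
    unit_diagonal: bool
    in_range: bool
    symmetric: bool
    psd: bool | None
    min_eigenvalue: float | None
    n_missing_pairs: int

    @property
    def is_valid(self) -> bool:
        """True when every checkable condition holds (PSD counts only if determinate)."""
        return (
            self.is_square
            and self.unit_diagonal
            and self.in_range
            and self.symmetric
            and self.psd is not False
        )


@dataclasses.dataclass(frozen=True)
class CholeskyFactor:
    """Lower-triangular factor L with L @ L.T reproducing the input matrix.

    ``undefined`` flags entries that could not be computed because they depend
    on a missing anchor correlation (at most L[p, p-1] and L[p, p], 1-based).
    """

    entries: np.ndarray
    undefined: np.ndarray

    @property
    def p(self) -> int:
        return self.entries.shape[0]

    @property
    def is_complete(self) -> bool:
        return not self.undefined.any()

    def matrix(self) -> np.ndarray:
        """Reconstruct L @ L.T (only meaningful when complete)."""
        return self.entries @ self.entries.T


def validate(M: CorMatrix | np.ndarray, psd_tol: float = PSD_TOL) -> ValidityReport:
    """Check the correlation-matrix validity conditions.

    The conditions are: square shape, unit diagonal, all entries in [-1, 1],
    symmetry, and positive semidefiniteness.  The PSD check runs only on a
    complete matrix (missing cells make the spectrum indeterminate).

    Parameters
    ----------
    M
        A :class:`CorMatrix` or any 2-d array-like.
    psd_tol
        Eigenvalues >= -psd_tol count as nonnegative.
    """
    arr = M.values if isinstance(M, CorMatrix) else np.asarray(M, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise DimensionError(
            f"matrix must be square, got {arr.shape[0] if arr.ndim == 2 else '?'} rows "
            f"and {arr.shape[1] if arr.ndim == 2 else '?'} columns (shape {arr.shape})"
        )
    mask = np.isnan(arr)
    diag = np.diagonal(arr)
    unit_diagonal = bool(np.all(~np.isnan(diag)) and np.allclose(diag, 1.0, rtol=0, atol=0))
    obs = ~mask
    both = obs & obs.T
    symmetric = bool(
        np.array_equal(mask, mask.T)
        and np.allclose(arr[both], arr.T[both], rtol=0, atol=0)
    )
    in_range = bool(np.all(np.abs(arr[obs]) <= 1.0))
    n_missing_pairs = int(np.tril(mask | mask.T, k=-1).sum())
    if mask.any():
        psd: bool | None = None
        min_eig: float | None = None
    else:
        min_eig = float(np.linalg.eigvalsh((arr + arr.T) / 2.0)[0])
        psd = bool(min_eig >= -psd_tol)
    return ValidityReport(
        is_square=True,
        unit_diagonal=unit_diagonal,
        in_range=in_range,
        symmetric=symmetric,
        psd=psd,
        min_eigenvalue=min_eig,
        n_missing_pairs=n_missing_pairs,
    )


def min_eigenvalue(M: CorMatrix | np.ndarray) -> float:
    """Smallest eigenvalue of the symmetrized matrix.

    Raises :class:`MissingPatternError` if any entry is missing.
    """
    arr = M.values if isinstance(M, CorMatrix) else np.asarray(M, dtype=float)
    if np.isnan(arr).any():
        raise MissingPatternError("cannot compute eigenvalues of a matrix with missing entries")
    return float(np.linalg.eigvalsh((arr + arr.T) / 2.0)[0])


def cholesky_crout(M: CorMatrix, chol_tol: float = CHOL_TOL) -> CholeskyFactor:
    """Column-by-column Cholesky factorization of a correlation matrix.

    Computes L with ``L[j,j] = sqrt(A[j,j] - sum_k<j L[j,k]^2)`` and
    ``L[i,j] = (A[i,j] - sum_k<j L[i,k] L[j,k]) / L[j,j]`` for i > j,
    starting from the upper-left corner.

    The input must be complete, or missing exactly the symmetric pair at the
    anchor position (p, p-1) in 1-based terms; in that case L[p, p-1] and
    L[p, p] are flagged undefined and every other entry is computed (none of
    them depends on the missing cell).

    A diagonal radicand in (-chol_tol, chol_tol] is clamped to zero: the
    matrix is semidefinite there, the variable is fully determined, and the
    entries below a zero pivot are set to zero.  A radicand below -chol_tol
    means the matrix is not PSD and raises :class:`DecompositionError`.
    """
    rep = validate(M)
    if not (rep.unit_diagonal and rep.in_range and rep.symmetric):
        raise ValidityError(
            "matrix fails validity checks before factorization: "
            f"unit_diagonal={rep.unit_diagonal}, in_range={rep.in_range}, "
            f"symmetric={rep.symmetric}"
        )
    p = M.p
    pairs = M.missing_pairs()
    if pairs and pairs != [(p, p - 1)]:
        bad = [pr for pr in pairs if pr != (p, p - 1)]
        raise MissingPatternError(
            f"missing entries at {bad} (1-based): only the anchor position "
            f"({p}, {p - 1}) may be missing; move the missing pair there first "
            "with a symmetric swap"
        )
    anchor_missing = bool(pairs)

    A = M.values
    L = np.zeros((p, p))
    undef = np.zeros((p, p), dtype=bool)
    for j in range(p):
        rad = A[j, j] - np.dot(L[j, :j], L[j, :j])
        if anchor_missing and j == p - 1:
            # the final diagonal entry depends on the missing anchor cell
            undef[j, j] = True
            L[j, j] = np.nan
            continue
        if rad < -chol_tol:
            raise DecompositionError(
                f"negative pivot {rad:.3e} in column {j + 1}: matrix is not "
                "positive semidefinite"
            )
        L[j, j] = np.sqrt(max(rad, 0.0))
        for i in range(j + 1, p):
            if anchor_missing and i == p - 1 and j == p - 2:
                undef[i, j] = True
                L[i, j] = np.nan
                continue
            if L[j, j] == 0.0:
                # zero pivot: variable j is fully determined, no freedom left
                L[i, j] = 0.0
            else:
                L[i, j] = (A[i, j] - np.dot(L[i, :j], L[j, :j])) / L[j, j]
    return CholeskyFactor(entries=L, undefined=undef)


# -- delimited-file round trip ----------------------------------------------


def read_cor_csv(
    path,
    *,
    header: bool = False,
    na_token: str = NA_TOKEN,
    delimiter: str = ",",
) -> CorMatrix:
    """Read a correlation matrix from a delimited text file.

    By default the file has no header row and uses ``NA`` for missing cells.
    """
    df = pd.read_csv(
        path,
        header=0 if header else None,
        na_values=[na_token],
        keep_default_na=False,
        sep=delimiter,
        index_col=None,
        float_precision="round_trip",
    )
    return CorMatrix(df.to_numpy(dtype=float), copy=False)


def write_cor_csv(
    M: CorMatrix,
    path,
    *,
    header: bool = False,
    na_token: str = NA_TOKEN,
    delimiter: str = ",",
    names: Sequence[str] | None = None,
) -> None:
    """Write a correlation matrix as delimited text, lossless at 17 significant digits."""
    cols: Iterable = names if names is not None else range(1, M.p + 1)
    df = pd.DataFrame(M.values, columns=[str(c) for c in cols])
    df.to_csv(
        path,
        header=header,
        index=False,
        na_rep=na_token,
        float_format="%.17g",
        sep=delimiter,
    )
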