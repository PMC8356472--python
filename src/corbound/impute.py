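"""Imputation of missing correlations from distributions over the feasible interval.

Once the feasible interval [lo, hi] for a missing correlation is known, a
point estimate can be taken at either endpoint or at the midpoint, or a
value can be sampled.  The sampling distribution is piecewise uniform over
fractions of the interval: breakpoints in [0, 1] split the interval into
sub-intervals, each carrying a probability mass, which lets any discrete
approximation of a prior be placed on the interval.  Because every value in
[lo, hi] completes the matrix to a valid (PSD) correlation matrix, imputed
matrices are valid by construction.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .boundary import BoundaryInterval, locate_missing, solve_boundary
from .corematrix import CorMatrix
from .errors import MissingPatternError, SpecificationError

_METHODS = ("min", "max", "midpoint", "uniform", "custom")


@dataclasses.dataclass(frozen=True)
class ImputeSpec:
    """How to pick a value inside the feasible interval.

    Parameters
    ----------
    method
        One of ``min``, ``max``, ``midpoint`` (deterministic) or ``uniform``,
        ``custom`` (stochastic).
    interval
        Increasing breakpoints in [0, 1], starting at 0 and ending at 1,
        expressed as fractions of the feasible interval.  Used only by
        ``custom``; e.g. ``(0, 0.4, 0.8, 1)`` defines three sub-intervals.
    interval_prob
        One non-negative weight per sub-interval, summing to 1.  E.g.
        ``(0.2, 0, 0.8)`` puts 20% of the mass on the first 40% of the
        interval and 80% on the last 20%, never sampling the middle.
    rng_seed
        Seed used when no explicit generator is passed to the sampler.
    """

    method: str
    interval: tuple[float, ...] = (0.0, 1.0)
    interval_prob: tuple[float, ...] = (1.0,)
    rng_seed: int = 0

    def __post_init__(self):
        if self.method not in _METHODS:
            raise SpecificationError(
                f"unknown method {self.method!r}; choose one of {_METHODS}"
            )
        object.__setattr__(self, "interval", tuple(float(x) for x in self.interval))
        object.__setattr__(
            self, "interval_prob", tuple(float(x) for x in self.interval_prob)
        )
        if self.method in ("uniform", "custom"):
            bp = np.asarray(self.interval)
            pr = np.asarray(self.interval_prob)
            if bp.size < 2:
                raise SpecificationError("interval needs at least two breakpoints")
            if bp[0] != 0.0 or bp[-1] != 1.0:
                raise SpecificationError(
                    f"breakpoints must start at 0 and end at 1, got {self.interval}"
                )
            if not np.all(np.diff(bp) > 0):
                raise SpecificationError(
                    f"breakpoints must be strictly increasing, got {self.interval}"
                )
            if pr.size != bp.size - 1:
                raise SpecificationError(
                    f"{pr.size} weights for {bp.size - 1} sub-intervals: need one "
                    "weight per sub-interval"
                )
            if (pr < 0).any():
                raise SpecificationError(f"negative weight in {self.interval_prob}")
            if abs(pr.sum() - 1.0) > 1e-12:
                raise SpecificationError(
                    f"weights must sum to 1 (got {pr.sum()!r})"
                )


def sample_fraction(spec: ImputeSpec, rng: np.random.Generator | None = None) -> float:
    """Draw a fraction of the feasible interval from the piecewise-uniform law.

    Selects sub-interval k with probability ``interval_prob[k]`` and then
    draws uniformly within it.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    pr = np.asarray(spec.interval_prob)
    k = int(rng.choice(pr.size, p=pr))
    lo, hi = spec.interval[k], spec.interval[k + 1]
    return float(rng.uniform(lo, hi))


def _impute_value(interval: BoundaryInterval, spec: ImputeSpec, rng) -> float:
    if spec.method == "min":
        return interval.lo
    if spec.method == "max":
        return interval.hi
    if spec.method == "midpoint":
        return interval.midpoint
    f = sample_fraction(spec, rng)
    return interval.lo + f * (interval.hi - interval.lo)


def cor_impute(
    M: CorMatrix,
    spec: ImputeSpec,
    rng: np.random.Generator | None = None,
    *,
    sequential: bool = False,
) -> CorMatrix:
    """Fill the missing correlation(s) of a matrix with plausible values.

    Computes the feasible interval with :func:`solve_boundary` and imputes
    according to ``spec``; both symmetric cells are filled and the completed
    matrix is valid (PSD up to tolerance) by construction.

    With ``sequential=True``, a matrix with several missing pairs is
    completed one pair at a time, narrowest feasible interval first — a
    documented heuristic, not a joint feasibility analysis.  Each candidate's
    interval is computed on the principal submatrix that excludes one index
    of every *other* missing pair, so the sub-problem has a single missing
    cell.
    """
    if rng is None and spec.method in ("uniform", "custom"):
        rng = np.random.default_rng(spec.rng_seed)
    pairs = M.missing_pairs()
    if not pairs:
        raise MissingPatternError("matrix is complete: nothing to impute")
    if len(pairs) == 1:
        interval = solve_boundary(M)
        value = _impute_value(interval, spec, rng)
        out = M.values.copy()
        out[interval.anchor_row - 1, interval.anchor_col - 1] = value
        out[interval.anchor_col - 1, interval.anchor_row - 1] = value
        return CorMatrix(out, copy=False)
    if not sequential:
        raise MissingPatternError(
            f"{len(pairs)} missing pairs: pass sequential=True to impute them "
            "one at a time (heuristic)"
        )
    current = M.copy()
    while True:
        pairs = current.missing_pairs()
        if not pairs:
            return current
        best: tuple[float, tuple[int, int]] | None = None
        for (i, j) in pairs:
            sub_iv = _subproblem_interval(current, (i, j), pairs)
            if best is None or sub_iv.width < best[0]:
                best = (sub_iv.width, (i, j))
        i, j = best[1]
        sub_iv = _subproblem_interval(current, (i, j), pairs)
        value = _impute_value(sub_iv, spec, rng)
        current.values[i - 1, j - 1] = value
        current.values[j - 1, i - 1] = value


def _subproblem_interval(
    M: CorMatrix, target: tuple[int, int], pairs: Sequence[tuple[int, int]]
) -> BoundaryInterval:
    """Feasible interval for one missing pair, other missing pairs excluded.

    For every other missing pair, one index not belonging to the target pair
    is dropped from the matrix, leaving a sub-matrix with a single missing
    cell that the analytic solver can handle.
    """
    i, j = target
    drop: set[int] = set()
    for (a, b) in pairs:
        if (a, b) == (i, j):
            continue
        drop.add(a if a not in (i, j) else b)
    keep = [k for k in range(1, M.p + 1) if k not in drop]
    idx = np.array(keep) - 1
    sub = CorMatrix(M.values[np.ix_(idx, idx)], copy=False)
    return solve_boundary(sub)
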