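import itertools

import numpy as np
import pytest

from corbound import (
    CorMatrix,
    boundary_oracle,
    cholesky_crout,
    cor_swap,
    locate_missing,
    min_eigenvalue,
    move_missing_to_anchor,
    random_valid_matrix,
    solve_boundary,
)
from corbound.errors import (
    DimensionError,
    InfeasibleError,
    MissingPatternError,
    ValidityError,
)
from .conftest import DEMO_HI, DEMO_LO, mask_pair


def complete(M: CorMatrix, value: float) -> CorMatrix:
    """Fill the single missing pair of M with value."""
    i, j = locate_missing(M)
    out = M.copy()
    out.values[i - 1, j - 1] = value
    out.values[j - 1, i - 1] = value
    return out


class TestCorSwap:
    def test_worked_example_two_swaps(self, demo_matrix, swapped_demo):
        out = cor_swap(cor_swap(demo_matrix, 1, 4), 2, 3)
        obs = ~np.isnan(out.values)
        assert np.array_equal(obs, ~np.isnan(swapped_demo.values))
        assert np.array_equal(out.values[obs], swapped_demo.values[obs])

    def test_self_swap_is_identity(self, demo_matrix):
        out = cor_swap(demo_matrix, 2, 2)
        assert np.array_equal(
            np.nan_to_num(out.values), np.nan_to_num(demo_matrix.values)
        )

    def test_swap_is_involution_and_preserves_eigenvalues(self):
        R = random_valid_matrix(5, 3)
        once = cor_swap(R, 1, 4)
        twice = cor_swap(once, 1, 4)
        assert np.array_equal(twice.values, R.values)
        assert np.allclose(
            np.linalg.eigvalsh(once.values), np.linalg.eigvalsh(R.values)
        )
        assert np.allclose(np.diag(once.values), 1.0)

    def test_index_out_of_range(self, demo_matrix):
        with pytest.raises(DimensionError, match="out of range"):
            cor_swap(demo_matrix, 0, 2)


class TestLocateMissing:
    def test_worked_example_position(self, demo_matrix):
        assert locate_missing(demo_matrix) == (2, 1)

    def test_complete_matrix_has_nothing_to_solve(self):
        with pytest.raises(MissingPatternError, match="nothing to solve"):
            locate_missing(CorMatrix.identity(3))

    def test_two_missing_pairs_directed_to_sequential_mode(self):
        M = mask_pair(mask_pair(random_valid_matrix(4, 5), 2, 1), 4, 3)
        with pytest.raises(MissingPatternError, match="sequential"):
            locate_missing(M)


class TestMoveMissingToAnchor:
    def test_worked_example_swap_sequence(self, demo_matrix):
        anchored, swaps = move_missing_to_anchor(demo_matrix)
        assert swaps == ((1, 4), (2, 3))
        assert locate_missing(anchored) == (4, 3)

    def test_already_anchored_needs_no_swap(self, swapped_demo):
        anchored, swaps = move_missing_to_anchor(swapped_demo)
        assert swaps == ()
        assert np.array_equal(
            np.nan_to_num(anchored.values), np.nan_to_num(swapped_demo.values)
        )

    def test_last_row_first_column_needs_one_swap(self):
        M = mask_pair(random_valid_matrix(4, 8), 4, 1)
        anchored, swaps = move_missing_to_anchor(M)
        assert swaps == ((1, 3),)
        assert locate_missing(anchored) == (4, 3)

    @pytest.mark.parametrize("p", [3, 4, 5, 6])
    def test_every_position_lands_at_anchor_in_at_most_two_swaps(self, p):
        """Enumerate all lower-triangle positions: the swap rule always anchors."""
        rng = np.random.default_rng(40 + p)
        base = random_valid_matrix(p, rng)
        for i in range(2, p + 1):
            for j in range(1, i):
                anchored, swaps = move_missing_to_anchor(mask_pair(base, i, j))
                assert len(swaps) <= 2
                assert locate_missing(anchored) == (p, p - 1)


class TestSolveBoundary:
    def test_worked_example_interval(self, demo_matrix):
        iv = solve_boundary(demo_matrix)
        assert iv.lo == pytest.approx(DEMO_LO, abs=5e-8)
        assert iv.hi == pytest.approx(DEMO_HI, abs=5e-8)
        assert (iv.anchor_row, iv.anchor_col) == (2, 1)

    def test_unconstrained_3x3_reaches_unit_bounds(self):
        M = CorMatrix([[1, 0, np.nan], [0, 1, 0], [np.nan, 0, 1.0]])
        iv = solve_boundary(M)
        assert iv.lo == pytest.approx(-1.0, abs=1e-12)
        assert iv.hi == pytest.approx(1.0, abs=1e-12)

    def test_3x3_strong_adjacent_correlations_narrow_interval(self):
        M = CorMatrix([[1, 0.9, np.nan], [0.9, 1, 0.9], [np.nan, 0.9, 1.0]])
        iv = solve_boundary(M)
        assert iv.lo == pytest.approx(0.81 - 0.19, abs=1e-10)
        assert iv.hi == pytest.approx(1.0, abs=1e-10)
        ref = boundary_oracle(M, step=1e-4)
        assert abs(iv.lo - ref.lo) <= 2e-4 and abs(iv.hi - ref.hi) <= 2e-4

    @pytest.mark.parametrize(
        "r12,r23",
        list(itertools.product([-0.9, -0.5, 0.0, 0.5, 0.9], repeat=2)),
    )
    def test_3x3_closed_form(self, r12, r23):
        """For p=3 the interval is r12*r23 +- sqrt((1-r12^2)(1-r23^2))."""
        M = CorMatrix(
            [[1, r12, np.nan], [r12, 1, r23], [np.nan, r23, 1.0]]
        )
        iv = solve_boundary(M)
        mid = r12 * r23
        half = np.sqrt((1 - r12**2) * (1 - r23**2))
        assert iv.lo == pytest.approx(mid - half, abs=1e-10)
        assert iv.hi == pytest.approx(mid + half, abs=1e-10)

    def test_partial_cholesky_identity_cross_check(self, demo_matrix):
        """The angle route equals the closed-form bound from the partial factor."""
        anchored, _ = move_missing_to_anchor(demo_matrix)
        L = cholesky_crout(anchored).entries
        p = anchored.p
        mid = float(np.dot(L[p - 1, : p - 2], L[p - 2, : p - 2]))
        half = float(
            L[p - 2, p - 2] * np.sqrt(1.0 - np.dot(L[p - 1, : p - 2], L[p - 1, : p - 2]))
        )
        iv = solve_boundary(demo_matrix)
        assert iv.lo == pytest.approx(mid - half, abs=1e-12)
        assert iv.hi == pytest.approx(mid + half, abs=1e-12)

    def test_permutation_invariance(self):
        """The interval does not depend on where the missing pair sits.

        Symmetric permutations relocate the missing pair without touching
        the correlations, so every permuted copy must yield the same bounds.
        """
        base = random_valid_matrix(5, 17)
        masked = mask_pair(base, 2, 1)
        iv0 = solve_boundary(masked)
        for seed in range(6):
            rng = np.random.default_rng(seed)
            m = masked
            for _ in range(3):
                a, b = rng.integers(1, 6, size=2)
                m = cor_swap(m, int(a), int(b))
            iv = solve_boundary(m)
            assert abs(iv.lo - iv0.lo) < 1e-12
            assert abs(iv.hi - iv0.hi) < 1e-12

    def test_degenerate_interval_collapses_to_point(self):
        """A determined variable leaves a single feasible value, not an error."""
        M = CorMatrix([[1, 1, np.nan], [1, 1, 0.5], [np.nan, 0.5, 1.0]])
        iv = solve_boundary(M)
        assert iv.lo == pytest.approx(iv.hi, abs=1e-12)
        assert iv.lo == pytest.approx(0.5, abs=1e-12)

    def test_invalid_observed_part_rejected(self):
        M = CorMatrix(
            [
                [1, 0.9, -0.9, np.nan],
                [0.9, 1, 0.9, 0.0],
                [-0.9, 0.9, 1, 0.0],
                [np.nan, 0.0, 0.0, 1.0],
            ]
        )
        with pytest.raises(ValidityError):
            solve_boundary(M)

    def test_endpoint_completion_is_singular(self, demo_matrix):
        iv = solve_boundary(demo_matrix)
        for v in (iv.lo, iv.hi):
            lam = min_eigenvalue(complete(demo_matrix, v))
            assert -1e-8 <= lam <= 1e-6


class TestBoundaryOracle:
    def test_worked_example_within_grid_resolution(self, demo_matrix):
        ref = boundary_oracle(demo_matrix, step=1e-4)
        assert ref.lo == pytest.approx(DEMO_LO, abs=1e-4)
        assert ref.hi == pytest.approx(DEMO_HI, abs=1e-4)

    def test_identity_with_one_missing_is_unconstrained(self):
        M = mask_pair(CorMatrix.identity(4), 3, 2)
        ref = boundary_oracle(M, step=1e-3)
        assert ref.lo == pytest.approx(-1.0, abs=1e-3)
        assert ref.hi == pytest.approx(1.0, abs=1e-3)

    def test_masked_true_value_is_feasible(self):
        R = random_valid_matrix(5, 21)
        true = R.values[3, 1]
        ref = boundary_oracle(mask_pair(R, 4, 2), step=1e-3)
        assert ref.lo - 1e-3 <= true <= ref.hi + 1e-3

    def test_infeasible_observed_part(self):
        M = CorMatrix(
            [
                [1, 0.9, -0.9, np.nan],
                [0.9, 1, 0.9, 0.0],
                [-0.9, 0.9, 1, 0.0],
                [np.nan, 0.0, 0.0, 1.0],
            ]
        )
        with pytest.raises(InfeasibleError):
            boundary_oracle(M, step=1e-2)

    def test_agrees_with_analytic_solver_on_fixtures(self):
        """Spot-check of the full-scale oracle-equivalence acceptance run."""
        rng = np.random.default_rng(0)
        for _ in range(40):
            p = int(rng.integers(3, 8))
            R = random_valid_matrix(p, rng)
            i = int(rng.integers(2, p + 1))
            j = int(rng.integers(1, i))
            masked = mask_pair(R, i, j)
            iv = solve_boundary(masked)
            ref = boundary_oracle(masked, step=1e-4)
            assert abs(iv.lo - ref.lo) <= 2e-4
            assert abs(iv.hi - ref.hi) <= 2e-4
            assert iv.lo - 1e-9 <= R.values[i - 1, j - 1] <= iv.hi + 1e-9
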