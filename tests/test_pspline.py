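"""P-spline basis, difference penalty, PWLS solver and smoothing selection."""

import numpy as np
import pytest

from ngri.pspline import (
    SplineSpec,
    build_basis,
    difference_penalty,
    lambda_for_edf,
    pwls_solve,
    select_lambda,
)


def cox_de_boor(x, t, i, k):
    """Textbook B-spline recursion, independent of the implementation under test."""
    if k == 0:
        return 1.0 if t[i] <= x < t[i + 1] else 0.0
    left = 0.0 if t[i + k] == t[i] else (x - t[i]) / (t[i + k] - t[i]) * cox_de_boor(x, t, i, k - 1)
    right = 0.0 if t[i + k + 1] == t[i + 1] else (
        (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * cox_de_boor(x, t, i + 1, k - 1)
    )
    return left + right


class TestBasis:
    def test_partition_of_unity(self):
        spec = SplineSpec()
        rng = np.random.default_rng(1)
        x = rng.uniform(18, 80, size=50)
        b = build_basis(x, spec)
        assert b.shape == (50, spec.n_basis)
        np.testing.assert_allclose(b.sum(axis=1), 1.0, atol=1e-12)

    def test_linear_hat_functions(self):
        # degree 1 with knots at the integers: halfway point splits 0.5/0.5
        spec = SplineSpec(degree=1, n_inner_knots=4, domain=(18.0, 23.0))
        b = build_basis([18.5], spec)[0]
        nz = b[b > 0]
        assert len(nz) == 2
        np.testing.assert_allclose(nz, [0.5, 0.5], atol=1e-12)

    def test_matches_cox_de_boor_recursion(self):
        spec = SplineSpec(degree=3, n_inner_knots=7, domain=(18.0, 80.0))
        t = spec.knots()
        rng = np.random.default_rng(2)
        xs = rng.uniform(18, 79.9, size=10)
        b = build_basis(xs, spec)
        for r, x in enumerate(xs):
            ref = [cox_de_boor(x, t, i, spec.degree) for i in range(spec.n_basis)]
            np.testing.assert_allclose(b[r], ref, atol=1e-10)

    def test_domain_policy(self):
        strict = SplineSpec(clamp=False)
        with pytest.raises(ValueError):
            build_basis([90.0], strict)
        clamped = build_basis([90.0], SplineSpec(clamp=True))
        boundary = build_basis([80.0], SplineSpec(clamp=True))
        np.testing.assert_allclose(clamped, boundary)


class TestPenalty:
    def test_second_difference_operator(self):
        p = difference_penalty(4, 2)
        d = np.array([[1, -2, 1, 0], [0, 1, -2, 1]], dtype=float)
        np.testing.assert_allclose(p, d.T @ d)

    def test_positive_semidefinite_with_null_space(self):
        for order in (1, 2, 3):
            p = difference_penalty(10, order)
            eig = np.linalg.eigvalsh(p)
            assert eig.min() > -1e-12
            assert np.sum(eig < 1e-10) == order

    def test_quadratic_form_is_sum_of_squared_differences(self):
        rng = np.random.default_rng(3)
        beta = rng.normal(size=12)
        p = difference_penalty(12, 2)
        assert beta @ p @ beta == pytest.approx(np.sum(np.diff(beta, n=2) ** 2), rel=1e-12)

    def test_too_small_basis_rejected(self):
        with pytest.raises(ValueError):
            difference_penalty(2, 2)


class TestPWLS:
    def _instance(self, n=50, seed=4):
        rng = np.random.default_rng(seed)
        x = rng.uniform(18, 80, size=n)
        spec = SplineSpec()
        b = build_basis(x, spec)
        y = np.sin(x / 10) + rng.normal(0, 0.1, size=n)
        w = rng.uniform(0.5, 2.0, size=n)
        return b, y, w, difference_penalty(spec.n_basis, 2)

    def test_huge_lambda_collapses_to_weighted_line(self):
        # order-2 penalty null space is {constant, linear}; 1e9 keeps the
        # normal equations numerically sane while shrinkage is complete
        rng = np.random.default_rng(4)
        x = rng.uniform(18, 80, size=60)
        y = 0.5 + 0.03 * x + rng.normal(0, 0.2, size=60)
        w = rng.uniform(0.5, 2.0, size=60)
        spec = SplineSpec()
        fit = pwls_solve(build_basis(x, spec), y, w, 1e9,
                         difference_penalty(spec.n_basis, 2))
        design = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(design.T @ (design * w[:, None]), design.T @ (w * y))
        np.testing.assert_allclose(fit.fitted, design @ beta, atol=1e-6)

    def test_zero_lambda_interpolates(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(18, 80, size=10))
        spec = SplineSpec(degree=3, n_inner_knots=6, domain=(18.0, 80.0))  # K = 10 = n
        b = build_basis(x, spec)
        y = rng.normal(size=10)
        fit = pwls_solve(b, y, np.ones(10), 0.0, difference_penalty(10, 2))
        np.testing.assert_allclose(fit.fitted, y, atol=1e-8)

    def test_matches_dense_normal_equations(self):
        b, y, w, p = self._instance()
        lam = 3.7
        fit = pwls_solve(b, y, w, lam, p)
        a = b.T @ (b * w[:, None]) + lam * p
        beta = np.linalg.solve(a, b.T @ (w * y))
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)
        h = b @ np.linalg.solve(a, (b * w[:, None]).T)
        assert fit.edf == pytest.approx(np.trace(h), abs=1e-8)

    def test_all_zero_weights_rejected(self):
        b, y, w, p = self._instance()
        with pytest.raises(ValueError):
            pwls_solve(b, y, np.zeros_like(y), 1.0, p)

    def test_edf_monotone_in_lambda(self):
        b, y, w, p = self._instance(n=100)
        edfs = [pwls_solve(b, y, w, lam, p).edf for lam in np.logspace(-4, 8, 25)]
        assert np.all(np.diff(edfs) <= 1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(18, 80, size=80)
        y = np.cos(x / 7) + rng.normal(0, 0.05, size=80)
        w = np.ones(80)
        f1 = pwls_solve(build_basis(x, SplineSpec()), y, w, 10.0,
                        difference_penalty(SplineSpec().n_basis, 2))
        shifted = SplineSpec(domain=(28.0, 90.0))
        f2 = pwls_solve(build_basis(x + 10, shifted), y, w, 10.0,
                        difference_penalty(shifted.n_basis, 2))
        np.testing.assert_allclose(f1.fitted, f2.fitted, atol=1e-8)


class TestSelection:
    def test_flat_truth_gives_null_space_edf(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(18, 80, size=500)
        y = 3.0 + rng.normal(0, 1.0, size=500)
        spec = SplineSpec()
        b = build_basis(x, spec)
        p = difference_penalty(spec.n_basis, 2)
        lam = select_lambda(b, y, np.ones(500), p)
        assert pwls_solve(b, y, np.ones(500), lam, p).edf < 2 + 1.5

    def test_curved_truth_gets_flexibility(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(18, 80, size=500)
        y = np.sin(x / 4.0) + rng.normal(0, 0.01, size=500)
        spec = SplineSpec()
        b = build_basis(x, spec)
        p = difference_penalty(spec.n_basis, 2)
        lam = select_lambda(b, y, np.ones(500), p)
        assert pwls_solve(b, y, np.ones(500), lam, p).edf > 6

    def test_returned_lambda_beats_grid_neighbours(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(18, 80, size=300)
        y = np.sin(x / 9.0) + rng.normal(0, 0.2, size=300)
        spec = SplineSpec()
        b = build_basis(x, spec)
        p = difference_penalty(spec.n_basis, 2)
        w = np.ones(300)
        lam = select_lambda(b, y, w, p)
        gcv = pwls_solve(b, y, w, lam, p).gcv
        grid = np.logspace(-4, 8, 61)
        i = int(np.argmin(np.abs(np.log10(grid) - np.log10(lam))))
        for j in (max(i - 1, 0), min(i + 1, 60)):
            assert gcv <= pwls_solve(b, y, w, grid[j], p).gcv + 1e-12

    def test_lambda_for_edf_hits_target(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(18, 80, size=400)
        spec = SplineSpec()
        b = build_basis(x, spec)
        p = difference_penalty(spec.n_basis, 2)
        for target in (3.0, 5.0, 8.0):
            lam = lambda_for_edf(b, np.ones(400), p, target)
            got = pwls_solve(b, np.zeros(400), np.ones(400), lam, p).edf
            assert got == pytest.approx(target, abs=0.01)
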