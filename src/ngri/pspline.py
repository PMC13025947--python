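"""Penalized B-splines (P-splines): basis, difference penalty, PWLS solver, GCV.

Eilers-Marx convention: equally spaced knots over the covariate domain,
extended ``degree`` knots beyond each boundary, with a discrete
difference penalty of configurable order on adjacent coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import solve


@dataclass(frozen=True)
class SplineSpec:
    """Basis layout: K = n_inner_knots + degree + 1 B-spline functions."""

    degree: int = 3
    n_inner_knots: int = 20
    penalty_order: int = 2
    domain: tuple[float, float] = (18.0, 80.0)
    clamp: bool = True  # clamp out-of-domain x to the boundary instead of erroring

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.n_inner_knots < 2:
            raise ValueError("n_inner_knots must be >= 2")
        if self.penalty_order < 1:
            raise ValueError("penalty_order must be >= 1")
        lo, hi = self.domain
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"domain must be finite with x_min < x_max, got {self.domain}")

    @property
    def n_basis(self) -> int:
        return self.n_inner_knots + self.degree + 1

    def knots(self) -> np.ndarray:
        """Full equally spaced knot vector including the degree-fold extension."""
        lo, hi = self.domain
        h = (hi - lo) / (self.n_inner_knots + 1)
        return lo + h * np.arange(-self.degree, self.n_inner_knots + 2 + self.degree)


def build_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the n x K B-spline design matrix at ages ``x``."""
    xarr = np.asarray(x, dtype=float)
    lo, hi = spec.domain
    if spec.clamp:
        xarr = np.clip(xarr, lo, hi)
    elif np.any(xarr < lo) or np.any(xarr > hi):
        raise ValueError(f"x outside domain [{lo}, {hi}] and clamping disabled")
    t = spec.knots()
    # nudge the right endpoint into the half-open last interval
    xeval = np.minimum(xarr, hi - 1e-12 * (hi - lo))
    dm = BSpline.design_matrix(xeval, t, spec.degree)
    return dm.toarray()[:, : spec.n_basis]


def difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    """P = D'D with D the ``order``-th difference operator on K coefficients."""
    if n_basis <= order:
        raise ValueError(f"need n_basis > order, got {n_basis} <= {order}")
    d = np.diff(np.eye(n_basis), n=order, axis=0)
    return d.T @ d


@dataclass
class PWLSFit:
    """Solution of one penalized weighted least-squares problem."""

    coefficients: np.ndarray
    lam: float
    edf: float
    gcv: float
    fitted: np.ndarray = field(repr=False)


def pwls_solve(basis: np.ndarray, y_work, w, lam: float, penalty: np.ndarray,
               gcv_gamma: float = 1.4) -> PWLSFit:
    """Solve (B'WB + lam*P) beta = B'W y_work; edf = tr(B (B'WB+lam P)^-1 B'W).

    The reported GCV score is n*RSS_w/(n - gamma*edf)^2 with gamma = 1.4 by
    default: the standard inflation (as in mgcv) that counters GCV's known
    tendency to undersmooth via its shallow minimum; gamma = 1 recovers the
    textbook criterion.
    """
    basis = np.asarray(basis, dtype=float)
    y_work = np.asarray(y_work, dtype=float)
    w = np.asarray(w, dtype=float)
    n, k = basis.shape
    if y_work.shape != (n,) or w.shape != (n,):
        raise ValueError("basis, y_work and w dimensions disagree")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be >= 0 with at least one positive")
    bw = basis * w[:, None]
    btwb = bw.T @ basis
    btwy = bw.T @ y_work
    a = btwb + lam * penalty
    try:
        beta = solve(a, btwy, assume_a="pos")
        edf = float(np.trace(solve(a, btwb, assume_a="pos")))
    except np.linalg.LinAlgError as err:
        raise ValueError(
            f"singular penalized system (lam={lam}): {err}; "
            "check weights and basis rank"
        ) from err
    fitted = basis @ beta
    rss_w = float(np.sum(w * (y_work - fitted) ** 2))
    denom = max(n - gcv_gamma * edf, 1e-8)
    gcv = n * rss_w / denom**2
    return PWLSFit(coefficients=beta, lam=float(lam), edf=edf, gcv=gcv, fitted=fitted)


def lambda_for_edf(basis: np.ndarray, w, penalty: np.ndarray, target_edf: float,
                   y_work=None) -> float:
    """Smoothing parameter whose penalized fit has the requested edf.

    edf(lambda) is continuous and monotone nonincreasing, so bisection on
    log10(lambda) converges; the response is irrelevant (edf depends only on
    basis, weights and penalty), a zero vector is used internally.
    """
    n = np.asarray(basis).shape[0]
    y0 = np.zeros(n) if y_work is None else np.asarray(y_work, dtype=float)
    lo, hi = -6.0, 14.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        edf = pwls_solve(basis, y0, w, 10.0**mid, penalty).edf
        if edf > target_edf:
            lo = mid
        else:
            hi = mid
    return float(10.0 ** (0.5 * (lo + hi)))


def select_lambda(
    basis: np.ndarray,
    y_work,
    w,
    penalty: np.ndarray,
    log10_range: tuple[float, float] = (-4.0, 8.0),
    n_grid: int = 61,
) -> float:
    """GCV-minimizing smoothing parameter: log10 grid + golden-section refinement."""
    grid = np.logspace(log10_range[0], log10_range[1], n_grid)
    gcvs = np.array([pwls_solve(basis, y_work, w, lam, penalty).gcv for lam in grid])
    i = int(np.argmin(gcvs))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    if lo == hi:
        return float(grid[i])
    # golden-section on log10 scale
    llo, lhi = np.log10(lo), np.log10(hi)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = llo, lhi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = pwls_solve(basis, y_work, w, 10.0**c, penalty).gcv
    fd = pwls_solve(basis, y_work, w, 10.0**d, penalty).gcv
    for _ in range(40):
        if b - a < 1e-4:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = pwls_solve(basis, y_work, w, 10.0**c, penalty).gcv
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = pwls_solve(basis, y_work, w, 10.0**d, penalty).gcv
    lam_ref = 10.0 ** ((a + b) / 2.0)
    # never return a refinement worse than the best grid point
    if pwls_solve(basis, y_work, w, lam_ref, penalty).gcv <= gcvs[i]:
        return float(lam_ref)
    return float(grid[i])
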