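"""Age-continuous BCCG centile model.

mu(age) and sigma(age) are penalized B-splines on the log link, nu is a
constant: the GAMLSS-style model behind continuous reference curves.  Fitting
alternates Fisher-scoring P-spline updates for mu and sigma (working response
= link predictor + score/weight, weights from a numeric second derivative of
the log-likelihood on the link scale) with a safeguarded 1-D Newton step for
nu, each update guarded by step-halving on the penalized global deviance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from ngri import bccg
from ngri.bccg import EvalMode, bccg_loglik
from ngri.pspline import (
    SplineSpec,
    build_basis,
    difference_penalty,
    lambda_for_edf,
    pwls_solve,
    select_lambda,
)

_ETA_H = 1e-4  # step for numeric link-scale information
_W_FLOOR = 1e-10


class ConvergenceError(RuntimeError):
    """Raised when the outer loop exhausts max_outer without meeting tol."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class FitControl:
    """Knobs of the outer penalized-likelihood loop."""

    min_n: int = 200
    tol: float = 1e-6
    max_outer: int = 50
    max_halvings: int = 10
    mu_link: str = "log"  # "log" (default, structurally positive) or "identity"
    mode: EvalMode = "lms"
    # smoothing selection: a fixed lambda wins over an edf target, which wins
    # over GCV.  Adult hematology trends are gentle, and over-flexible medians
    # inflate edge variance, so the default targets a small effective df
    # (classical LMS practice); set edf targets to None to select by GCV.
    edf_mu: float | None = 3.5
    edf_sigma: float | None = 3.0
    reselect_lambda: bool = False  # re-run GCV every outer iteration
    fixed_lambda_mu: float | None = None
    fixed_lambda_sigma: float | None = None
    nu_bounds: tuple[float, float] = (-10.0, 10.0)


@dataclass
class CentileModel:
    """Fitted per-sex, per-analyte centile model."""

    analyte: str
    sex: str
    spec_mu: SplineSpec
    spec_sigma: SplineSpec
    beta_mu: np.ndarray
    beta_sigma: np.ndarray
    nu: float
    lambdas: tuple[float, float]
    links: tuple[str, str]
    mode: EvalMode
    convergence: dict = field(default_factory=dict)

    def mu(self, ages) -> np.ndarray:
        eta = build_basis(ages, self.spec_mu) @ self.beta_mu
        return np.exp(eta) if self.links[0] == "log" else eta

    def sigma(self, ages) -> np.ndarray:
        return np.exp(build_basis(ages, self.spec_sigma) @ self.beta_sigma)

    def to_json(self) -> str:
        payload = {
            "analyte": self.analyte,
            "sex": self.sex,
            "spec_mu": asdict(self.spec_mu),
            "spec_sigma": asdict(self.spec_sigma),
            "beta_mu": self.beta_mu.tolist(),
            "beta_sigma": self.beta_sigma.tolist(),
            "nu": self.nu,
            "lambdas": list(self.lambdas),
            "links": list(self.links),
            "mode": self.mode,
            "convergence": self.convergence,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CentileModel":
        d = json.loads(text)
        for key in ("spec_mu", "spec_sigma"):
            d[key]["domain"] = tuple(d[key]["domain"])
        return cls(
            analyte=d["analyte"],
            sex=d["sex"],
            spec_mu=SplineSpec(**d["spec_mu"]),
            spec_sigma=SplineSpec(**d["spec_sigma"]),
            beta_mu=np.asarray(d["beta_mu"]),
            beta_sigma=np.asarray(d["beta_sigma"]),
            nu=float(d["nu"]),
            lambdas=tuple(d["lambdas"]),
            links=tuple(d["links"]),
            mode=d["mode"],
            convergence=d["convergence"],
        )


def _loglik(y, mu, sigma, nu, mode) -> float:
    with np.errstate(all="ignore"):
        try:
            return bccg_loglik(y, mu, sigma, nu, mode)
        except ValueError:
            return -np.inf


def _pen_dev(y, basis_mu, basis_sigma, beta_mu, beta_sigma, nu, lam, pens, links, mode):
    eta_mu = basis_mu @ beta_mu
    eta_sigma = basis_sigma @ beta_sigma
    mu = np.exp(eta_mu) if links[0] == "log" else eta_mu
    sigma = np.exp(eta_sigma)
    if links[0] == "identity" and np.any(mu <= 0):
        return np.inf
    ll = _loglik(y, mu, sigma, nu, mode)
    pen = lam[0] * beta_mu @ pens[0] @ beta_mu + lam[1] * beta_sigma @ pens[1] @ beta_sigma
    dev = -2.0 * ll + pen
    return dev if np.isfinite(dev) else np.inf


def _eta_score_weight(y, eta, other, nu, which, link, mode):
    """Score and numeric Fisher weight on the link scale for mu or sigma."""

    def score_eta(e):
        if which == "mu":
            mu = np.exp(e) if link == "log" else e
            d_mu, _, _ = bccg.score_arrays(y, mu, other, nu, mode)
            return d_mu * mu if link == "log" else d_mu
        sigma = np.exp(e)
        _, d_sigma, _ = bccg.score_arrays(y, other, sigma, nu, mode)
        return d_sigma * sigma

    u = score_eta(eta)
    w = -(score_eta(eta + _ETA_H) - score_eta(eta - _ETA_H)) / (2.0 * _ETA_H)
    bad = ~np.isfinite(w) | (w <= 0)
    w = np.where(bad, u * u, w)  # quasi-Fisher fallback
    w = np.maximum(w, _W_FLOOR)
    return u, w


def _halved_update(y, bm, bs, beta_mu, beta_sigma, nu, lam, pens, links, mode,
                   which, beta_new, dev_old, max_halvings):
    """Blend towards beta_new, halving the step until deviance does not worsen."""
    beta_old = beta_mu if which == "mu" else beta_sigma
    step = 1.0
    for _ in range(max_halvings + 1):
        cand = beta_old + step * (beta_new - beta_old)
        if which == "mu":
            dev = _pen_dev(y, bm, bs, cand, beta_sigma, nu, lam, pens, links, mode)
        else:
            dev = _pen_dev(y, bm, bs, beta_mu, cand, nu, lam, pens, links, mode)
        if dev <= dev_old + 1e-10 * (1.0 + abs(dev_old)):
            return cand, dev
        step *= 0.5
    return beta_old, dev_old


def fit_centile_model(
    ages,
    values,
    spec: SplineSpec | tuple[SplineSpec, SplineSpec] = SplineSpec(),
    control: FitControl = FitControl(),
    analyte: str = "analyte",
    sex: str = "unspecified",
) -> CentileModel:
    """Fit mu(age), sigma(age) splines and constant nu by penalized likelihood.

    Observations are sorted by (age, value) internally, so the fit is invariant
    to input order; with no randomness anywhere, refits are bit-identical.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if ages.shape != y.shape or ages.ndim != 1:
        raise ValueError("ages and values must be 1-D arrays of equal length")
    if len(y) < control.min_n:
        raise ValueError(f"need at least min_n={control.min_n} observations, got {len(y)}")
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("values must be finite and > 0")
    if np.ptp(y) == 0:
        raise ValueError("degenerate data: all values identical")
    order = np.lexsort((y, ages))
    ages, y = ages[order], y[order]

    spec_mu, spec_sigma = (spec, spec) if isinstance(spec, SplineSpec) else spec
    bm = build_basis(ages, spec_mu)
    bs = build_basis(ages, spec_sigma)
    pens = (
        difference_penalty(spec_mu.n_basis, spec_mu.penalty_order),
        difference_penalty(spec_sigma.n_basis, spec_sigma.penalty_order),
    )
    links = (control.mu_link, "log")
    mode = control.mode

    # --- initialization: smooth of log y for mu, constant sigma, nu = 1
    logy = np.log(y)
    ones = np.ones_like(y)
    if control.fixed_lambda_mu is not None:
        lam_mu = control.fixed_lambda_mu
    elif control.edf_mu is not None:
        lam_mu = lambda_for_edf(bm, ones, pens[0], control.edf_mu)
    else:
        lam_mu = select_lambda(bm, logy, ones, pens[0])
    init_mu_fit = pwls_solve(bm, logy, ones, lam_mu, pens[0])
    if links[0] == "log":
        beta_mu = init_mu_fit.coefficients
    else:
        beta_mu = pwls_solve(bm, np.exp(init_mu_fit.fitted), ones, lam_mu, pens[0]).coefficients
    sigma0 = max(float(np.std(logy)), 1e-4)
    beta_sigma = np.full(spec_sigma.n_basis, np.log(sigma0))
    nu = 1.0

    # sigma smoothing parameter from the working weights at the initial state
    if control.fixed_lambda_sigma is not None:
        lam_sigma = control.fixed_lambda_sigma
    else:
        eta_mu = bm @ beta_mu
        mu_cur = np.exp(eta_mu) if links[0] == "log" else eta_mu
        eta_s = bs @ beta_sigma
        u, w = _eta_score_weight(y, eta_s, mu_cur, nu, "sigma", "log", mode)
        if control.edf_sigma is not None:
            lam_sigma = lambda_for_edf(bs, w, pens[1], control.edf_sigma)
        else:
            lam_sigma = select_lambda(bs, eta_s + u / w, w, pens[1])
    lam = (float(lam_mu), float(lam_sigma))

    dev = _pen_dev(y, bm, bs, beta_mu, beta_sigma, nu, lam, pens, links, mode)
    trace = [dev]
    converged = False
    n_iter = 0
    for n_iter in range(1, control.max_outer + 1):
        if control.reselect_lambda and n_iter > 1:
            eta_mu = bm @ beta_mu
            mu_cur = np.exp(eta_mu) if links[0] == "log" else eta_mu
            sig_cur = np.exp(bs @ beta_sigma)
            u, w = _eta_score_weight(y, eta_mu, sig_cur, nu, "mu", links[0], mode)
            lam = (select_lambda(bm, eta_mu + u / w, w, pens[0]), lam[1])
            eta_s = bs @ beta_sigma
            u, w = _eta_score_weight(y, eta_s, mu_cur, nu, "sigma", "log", mode)
            lam = (lam[0], select_lambda(bs, eta_s + u / w, w, pens[1]))

        # mu update
        eta_mu = bm @ beta_mu
        sig_cur = np.exp(bs @ beta_sigma)
        u, w = _eta_score_weight(y, eta_mu, sig_cur, nu, "mu", links[0], mode)
        new_beta = pwls_solve(bm, eta_mu + u / w, w, lam[0], pens[0]).coefficients
        beta_mu, dev = _halved_update(
            y, bm, bs, beta_mu, beta_sigma, nu, lam, pens, links, mode,
            "mu", new_beta, dev, control.max_halvings,
        )

        # sigma update
        eta_mu = bm @ beta_mu
        mu_cur = np.exp(eta_mu) if links[0] == "log" else eta_mu
        eta_s = bs @ beta_sigma
        u, w = _eta_score_weight(y, eta_s, mu_cur, nu, "sigma", "log", mode)
        new_beta = pwls_solve(bs, eta_s + u / w, w, lam[1], pens[1]).coefficients
        beta_sigma, dev = _halved_update(
            y, bm, bs, beta_mu, beta_sigma, nu, lam, pens, links, mode,
            "sigma", new_beta, dev, control.max_halvings,
        )

        # nu update: safeguarded Newton on the profile likelihood
        sig_cur = np.exp(bs @ beta_sigma)
        nu, dev = _newton_nu(
            y, mu_cur, sig_cur, nu, dev,
            lam, pens, beta_mu, beta_sigma, mode, control,
        )

        trace.append(dev)
        rel = abs(trace[-2] - dev) / (abs(trace[-2]) + 1e-10)
        if rel < control.tol:
            converged = True
            break

    if not converged:
        raise ConvergenceError(
            f"no convergence in {control.max_outer} outer iterations "
            f"(last rel change {rel:.3e})",
            trace,
        )
    return CentileModel(
        analyte=analyte,
        sex=sex,
        spec_mu=spec_mu,
        spec_sigma=spec_sigma,
        beta_mu=beta_mu,
        beta_sigma=beta_sigma,
        nu=float(nu),
        lambdas=lam,
        links=links,
        mode=mode,
        convergence={
            "n_outer_iterations": n_iter,
            "final_deviance": float(dev),
            "converged": True,
        },
    )


def _newton_nu(y, mu, sigma, nu, dev_old, lam, pens, beta_mu, beta_sigma, mode, control):
    pen = lam[0] * beta_mu @ pens[0] @ beta_mu + lam[1] * beta_sigma @ pens[1] @ beta_sigma
    h = 1e-4
    lo, hi = control.nu_bounds

    def negdev(v):  # penalized deviance as a function of nu alone
        return -2.0 * _loglik(y, mu, sigma, v, mode) + pen

    f0 = negdev(nu)
    fp = negdev(nu + h)
    fm = negdev(nu - h)
    g = (fp - fm) / (2.0 * h)
    hess = (fp - 2.0 * f0 + fm) / (h * h)
    step = -g / hess if hess > 0 else -np.sign(g) * 0.1
    step = float(np.clip(step, -0.5, 0.5))
    for _ in range(control.max_halvings + 1):
        cand = float(np.clip(nu + step, lo, hi))
        dev = negdev(cand)
        if dev <= f0 + 1e-10 * (1.0 + abs(f0)):
            return cand, dev
        step *= 0.5
    return nu, dev_old


def predict_centiles(model: CentileModel, ages, percentiles: Sequence[float]) -> np.ndarray:
    """Matrix of model quantiles, shape (len(ages), len(percentiles))."""
    ps = np.asarray(percentiles, dtype=float)
    if np.any(ps <= 0) or np.any(ps >= 1):
        raise ValueError("percentiles must lie strictly in (0, 1)")
    mu = np.atleast_1d(model.mu(ages))
    sigma = np.atleast_1d(model.sigma(ages))
    out = np.empty((len(mu), len(ps)))
    for j, p in enumerate(ps):
        out[:, j] = _quantile_arrays(p, mu, sigma, model.nu, model.mode)
    return out


def _quantile_arrays(p: float, mu, sigma, nu, mode):
    from scipy import stats

    if abs(nu) < 1e-8:
        return mu * np.exp(sigma * stats.norm.ppf(p))
    if mode == "exact":
        c = stats.norm.cdf(1.0 / (sigma * abs(nu)))
        padj = p * c + (1.0 - c) if nu > 0 else p * c
    else:
        padj = p
    z = stats.norm.ppf(padj)
    base = 1.0 + nu * sigma * z
    if np.any(base <= 0):
        raise ValueError(f"quantile undefined at p={p} for fitted parameters")
    return mu * np.power(base, 1.0 / nu)


def global_deviance(model: CentileModel, ages, values) -> float:
    """-2 * log-likelihood of the data under the fitted model."""
    mu = model.mu(ages)
    sigma = model.sigma(ages)
    return -2.0 * bccg_loglik(values, mu, sigma, model.nu, model.mode)
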