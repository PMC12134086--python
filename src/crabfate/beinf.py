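"""Zero-one-inflated beta (BEINF) distribution and regression.

Turnover proportions observed on tagged colonies pile up at exactly 0 (no
change) and exactly 1 (complete replacement of the crab cohort), with a
continuous beta-distributed interior.  The BEINF distribution handles this
with a three-part mixture:

* point mass ``nu`` at 0,
* point mass ``(1 - nu) * tau`` at 1,
* density ``(1 - nu) * (1 - tau) * Beta(y; a, b)`` on (0, 1),

where the beta component is parameterized by its mean ``mu`` and a dispersion
parameter ``sigma`` in (0, 1) through ``a = mu * (1 - sigma^2) / sigma^2`` and
``b = (1 - mu) * (1 - sigma^2) / sigma^2`` (precision ``a + b`` decreases as
``sigma`` grows).  ``nu`` is the probability of a zero and ``tau`` the
probability of a one given the value is non-zero, so the three cell
probabilities always sum to 1.

The regression puts a logit link on ``mu`` with site and time-point fixed
effects, a logit link on ``sigma``, and intercept-only logits ``alpha0`` and
``gamma0`` on ``nu`` and ``tau``.  Because the inflation parts are
intercept-only, their maximum-likelihood estimates are the boundary-count
proportions and the likelihood separates; the beta part is maximized
numerically (multi-start quasi-Newton with a Newton polish).  Wald standard
errors come from the numerical Hessian of the joint log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess

from .exceptions import DegenerateFitError

__all__ = [
    "BEINFParams",
    "BEINFFit",
    "beinf_shapes",
    "beinf_density",
    "beinf_logpdf",
    "beinf_loglik",
    "fit_beinf",
    "predict_mu",
]


def beinf_shapes(mu, sigma):
    """Map (mean, dispersion) to beta shape parameters (a, b)."""
    phi = (1.0 - sigma**2) / sigma**2
    return mu * phi, (1.0 - mu) * phi


def _check_params(mu, sigma, nu, tau) -> None:
    mu = np.asarray(mu, dtype=float)
    if ((mu <= 0) | (mu >= 1)).any():
        raise ValueError("mu must lie strictly inside (0, 1)")
    if not (0.0 < sigma < 1.0):
        raise ValueError(f"sigma must lie in (0, 1), got {sigma}")
    for name, v in (("nu", nu), ("tau", tau)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")


def beinf_density(y, mu, sigma, nu, tau):
    """Density (0 < y < 1) or point mass (y in {0, 1}) of BEINF(mu, sigma, nu, tau)."""
    _check_params(mu, sigma, nu, tau)
    y_arr = np.asarray(y, dtype=float)
    if ((y_arr < 0) | (y_arr > 1)).any():
        raise ValueError("y must lie in [0, 1]")
    mu_arr = np.broadcast_to(np.asarray(mu, dtype=float), y_arr.shape)
    a, b = beinf_shapes(mu_arr, sigma)
    with np.errstate(divide="ignore", invalid="ignore"):
        cont = (1.0 - nu) * (1.0 - tau) * stats.beta.pdf(y_arr, a, b)
    out = np.where(y_arr == 0.0, nu, np.where(y_arr == 1.0, (1.0 - nu) * tau, cont))
    return out if out.shape else float(out)


def beinf_logpdf(y, mu, sigma, nu, tau):
    """Log of :func:`beinf_density`; -inf where the mass/density is zero."""
    with np.errstate(divide="ignore"):
        return np.log(beinf_density(y, mu, sigma, nu, tau))


def beinf_loglik(y, mu, sigma, nu, tau) -> float:
    """Total log-likelihood; returns -inf if any observation has zero density."""
    lp = np.asarray(beinf_logpdf(y, mu, sigma, nu, tau))
    if np.isnan(lp).any():
        return -np.inf
    total = lp.sum()
    return float(total) if np.isfinite(total) else -np.inf


# ---------------------------------------------------------------------------
# Parameters / fit containers


@dataclass
class BEINFParams:
    """Coefficients and distribution parameters of a BEINF regression.

    ``beta_mu`` holds the logit-scale coefficients for the mean, ordered as
    ``coef_names`` (intercept first, then site and time-point effect codes
    relative to the baseline levels).
    """

    beta_mu: np.ndarray
    sigma: float
    nu: float
    tau: float
    coef_names: tuple[str, ...] = ("intercept",)
    baseline_site: str | None = None
    baseline_time_point: str | None = None
    site_levels: tuple[str, ...] = ()
    time_levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.beta_mu = np.atleast_1d(np.asarray(self.beta_mu, dtype=float))
        _check_params(0.5, self.sigma, self.nu, self.tau)

    @property
    def link_alpha0(self) -> float:
        """Logit intercept for the zero-inflation probability."""
        return float(special.logit(self.nu))

    @property
    def link_gamma0(self) -> float:
        """Logit intercept for the conditional one-inflation probability."""
        return float(special.logit(self.tau))

    def design_row(self, site: str | None, time_point) -> np.ndarray:
        row = np.zeros(len(self.coef_names))
        row[0] = 1.0
        names = list(self.coef_names)
        if site is not None and site != self.baseline_site:
            key = f"site[{site}]"
            if key not in names:
                raise ValueError(f"unknown site level {site!r}")
            row[names.index(key)] = 1.0
        if time_point is not None and str(time_point) != str(self.baseline_time_point):
            key = f"time_point[{time_point}]"
            if key not in names:
                raise ValueError(f"unknown time-point level {time_point!r}")
            row[names.index(key)] = 1.0
        return row

    def mu_for_design(self, design: pd.DataFrame | None) -> np.ndarray:
        if design is None:
            return special.expit(np.atleast_1d(self.beta_mu[0]))
        rows = np.stack(
            [
                self.design_row(
                    r.get("site") if "site" in design.columns else None,
                    r.get("time_point") if "time_point" in design.columns else None,
                )
                for r in design.to_dict(orient="records")
            ]
        )
        return special.expit(rows @ self.beta_mu)


@dataclass
class BEINFFit:
    """Maximum-likelihood fit of the BEINF regression."""

    params: BEINFParams
    loglik: float
    standard_errors: dict[str, float]
    wald_p: dict[str, float]
    converged: bool
    n_obs: int
    n_zero: int
    n_one: int

    @property
    def n_params(self) -> int:
        k = len(self.params.beta_mu) + 1  # beta coefficients + sigma
        k += int(self.n_zero > 0) + int(self.n_one > 0)
        return k

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    def to_dict(self) -> dict:
        p = self.params
        estimates = {name: float(b) for name, b in zip(p.coef_names, p.beta_mu)}
        estimates.update({"sigma": p.sigma, "nu": p.nu, "tau": p.tau})
        return {
            "estimates": estimates,
            "standard_errors": {k: float(v) for k, v in self.standard_errors.items()},
            "wald_p": {k: float(v) for k, v in self.wald_p.items()},
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "converged": bool(self.converged),
            "n_obs": self.n_obs,
            "n_zero": self.n_zero,
            "n_one": self.n_one,
            "baseline_site": p.baseline_site,
            "baseline_time_point": p.baseline_time_point,
        }


# ---------------------------------------------------------------------------
# Design matrix


def _build_design(
    n: int,
    site: Sequence | None,
    time_point: Sequence | None,
    baseline_site: str | None,
) -> tuple[np.ndarray, list[str], dict]:
    cols = [np.ones(n)]
    names = ["intercept"]
    meta: dict = {
        "baseline_site": None,
        "baseline_time_point": None,
        "site_levels": (),
        "time_levels": (),
    }
    if site is not None:
        site = pd.Series(site).astype(str).to_numpy()
        levels = sorted(set(site))
        base = baseline_site if baseline_site is not None else levels[0]
        if base not in levels:
            raise ValueError(f"baseline site {base!r} not among levels {levels}")
        meta["baseline_site"] = base
        meta["site_levels"] = tuple(levels)
        for lev in levels:
            if lev == base:
                continue
            cols.append((site == lev).astype(float))
            names.append(f"site[{lev}]")
    if time_point is not None:
        tp = pd.Series(time_point).astype(str).to_numpy()
        levels = sorted(set(tp))
        meta["baseline_time_point"] = levels[0]
        meta["time_levels"] = tuple(levels)
        for lev in levels[1:]:
            cols.append((tp == lev).astype(float))
            names.append(f"time_point[{lev}]")
    return np.column_stack(cols), names, meta


# ---------------------------------------------------------------------------
# Fitting


def _beta_negll(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    beta, s = theta[:-1], theta[-1]
    sigma = special.expit(s)
    mu = special.expit(X @ beta)
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    sigma = min(max(sigma, eps), 1 - eps)
    a, b = beinf_shapes(mu, sigma)
    ll = stats.beta.logpdf(y, a, b).sum()
    return 1e10 if not np.isfinite(ll) else -float(ll)


def _central_grad(f, x: np.ndarray, step: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(x)
    for i in range(len(x)):
        h = step * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g


def fit_beinf(
    y: Sequence[float],
    site: Sequence | None = None,
    time_point: Sequence | None = None,
    baseline_site: str | None = None,
    max_iter: int = 500,
    tol: float = 1e-10,
    n_starts: int = 3,
    start_seed: int = 0,
) -> BEINFFit:
    """Fit the BEINF regression by maximum likelihood.

    ``y`` holds proportions in [0, 1] (exact zeros and ones allowed); ``site``
    and ``time_point`` are optional factors entering the mean's logit link as
    fixed effects, with the baseline site the alphabetically first level
    unless ``baseline_site`` is given.

    Raises
    ------
    DegenerateFitError
        If no observation falls strictly inside (0, 1), leaving the beta
        component unidentified (this covers data sitting entirely on one
        boundary or split between the two).
    """
    y = np.asarray(y, dtype=float)
    if ((y < 0) | (y > 1)).any():
        raise ValueError("responses must lie in [0, 1]")
    n = len(y)
    if n == 0:
        raise ValueError("empty response")

    is0, is1 = y == 0.0, y == 1.0
    n_zero, n_one = int(is0.sum()), int(is1.sum())
    cont = ~(is0 | is1)
    if not cont.any():
        raise DegenerateFitError(
            "all observations sit on the {0, 1} boundaries; the continuous beta "
            "component cannot be estimated"
        )

    X, names, meta = _build_design(n, site, time_point, baseline_site)
    Xc, yc = X[cont], y[cont]
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise DegenerateFitError(
            "design matrix is rank-deficient on the continuous observations; "
            "ensure every factor level has interior responses"
        )

    # Inflation MLEs are closed-form for intercept-only links.
    nu_hat = n_zero / n
    tau_hat = n_one / (n - n_zero) if n > n_zero else 0.0

    # Moment-based start for the beta part.
    m = float(np.mean(yc))
    v = float(np.var(yc)) if len(yc) > 1 else 0.01
    sigma0 = np.sqrt(np.clip(v / max(m * (1 - m), 1e-8), 1e-3, 0.9))
    theta0 = np.zeros(Xc.shape[1] + 1)
    theta0[0] = special.logit(np.clip(m, 1e-6, 1 - 1e-6))
    theta0[-1] = special.logit(np.clip(sigma0, 1e-6, 1 - 1e-6))

    rng = np.random.default_rng(start_seed)
    best = None
    converged = False
    for k in range(max(1, n_starts)):
        start = theta0 if k == 0 else theta0 + rng.normal(0.0, 0.3, size=theta0.shape)
        res = optimize.minimize(
            _beta_negll,
            start,
            args=(Xc, yc),
            method="BFGS",
            options={"gtol": 1e-9, "maxiter": max_iter},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success) or np.max(np.abs(res.jac)) < 1e-5 * max(1, len(yc))

    theta = best.x
    # Newton polish to drive the gradient toward machine precision.
    f = lambda th: _beta_negll(th, Xc, yc)
    for _ in range(30):
        g = _central_grad(f, theta)
        if np.max(np.abs(g)) < tol * max(1.0, len(yc)):
            converged = True
            break
        H = approx_hess(theta, f)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        new = theta - step
        if not np.isfinite(f(new)) or f(new) > f(theta) + 1e-9:
            # fall back to a damped step
            for damp in (0.5, 0.25, 0.1):
                cand = theta - damp * step
                if f(cand) < f(theta):
                    new = cand
                    break
            else:
                break
        if np.max(np.abs(new - theta)) < 1e-14:
            theta = new
            converged = True
            break
        theta = new
    if np.max(np.abs(_central_grad(f, theta))) < 1e-5 * max(1.0, len(yc)):
        converged = True

    beta_hat = theta[:-1]
    sigma_hat = float(special.expit(theta[-1]))

    params = BEINFParams(
        beta_mu=beta_hat,
        sigma=sigma_hat,
        nu=nu_hat,
        tau=tau_hat,
        coef_names=tuple(names),
        baseline_site=meta["baseline_site"],
        baseline_time_point=meta["baseline_time_point"],
        site_levels=meta["site_levels"],
        time_levels=meta["time_levels"],
    )

    # Joint log-likelihood at the MLE.
    mu_all = special.expit(X @ beta_hat)
    ll = 0.0
    if n_zero:
        ll += n_zero * np.log(nu_hat)
    if n - n_zero:
        if n_one:
            ll += n_one * (np.log1p(-nu_hat) + np.log(tau_hat))
        ll += cont.sum() * (np.log1p(-nu_hat) + np.log1p(-tau_hat))
    a, b = beinf_shapes(np.clip(mu_all[cont], 1e-12, 1 - 1e-12), sigma_hat)
    ll += float(stats.beta.logpdf(yc, a, b).sum())

    ses, pvals = _wald(theta, Xc, yc, names, n, n_zero, n_one, nu_hat, tau_hat)

    return BEINFFit(
        params=params,
        loglik=float(ll),
        standard_errors=ses,
        wald_p=pvals,
        converged=converged,
        n_obs=n,
        n_zero=n_zero,
        n_one=n_one,
    )


def _wald(theta, Xc, yc, names, n, n_zero, n_one, nu_hat, tau_hat):
    """Wald SEs/p-values from the numerical Hessian of the joint likelihood.

    The joint information matrix is block-diagonal between the beta part
    (beta coefficients, logit sigma) and the two inflation intercepts, so the
    blocks are inverted separately.  Inflation SEs are reported on the logit
    scale (alpha0, gamma0); they are undefined when a boundary count is 0.
    """
    labels = list(names) + ["logit_sigma", "alpha0", "gamma0"]
    ses: dict[str, float] = {}
    pvals: dict[str, float] = {}

    H = approx_hess(theta, lambda th: _beta_negll(th, Xc, yc))
    try:
        cov = np.linalg.inv(H)
        se_beta = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_beta = np.full(len(theta), np.nan)
    for lab, est, se in zip(labels, theta, se_beta):
        ses[lab] = float(se)
        z = est / se if se and np.isfinite(se) and se > 0 else np.nan
        pvals[lab] = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan

    # Bernoulli information for logit intercepts: I(alpha0) = m * p * (1 - p).
    for lab, p_hat, m in (("alpha0", nu_hat, n), ("gamma0", tau_hat, n - n_zero)):
        if 0.0 < p_hat < 1.0 and m > 0:
            se = 1.0 / np.sqrt(m * p_hat * (1 - p_hat))
            est = special.logit(p_hat)
            ses[lab] = float(se)
            pvals[lab] = float(2 * stats.norm.sf(abs(est / se)))
        else:
            ses[lab] = float("nan")
            pvals[lab] = float("nan")
    return ses, pvals


def predict_mu(fit: BEINFFit, site: str | None = None, time_point=None) -> float:
    """Mean turnover proportion (inverse-logit of the linear predictor)."""
    row = fit.params.design_row(site, time_point)
    return float(special.expit(row @ fit.params.beta_mu))
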