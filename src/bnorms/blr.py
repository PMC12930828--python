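"""Warped Bayesian linear regression (the normative-modelling engine).

A Gaussian Bayesian linear regression with an isotropic zero-mean prior
``w ~ N(0, alpha^{-1} I)`` and noise precision ``beta`` is fitted not to the
raw response but to its sinh-arcsinh warp ``g(y; a, b)``. The four
hyperparameters ``(alpha, beta, a, b)`` are set by type-II maximum
likelihood: the Gaussian model evidence on the warped response, times the
warp Jacobian, is maximised with Powell's method over
``(log alpha, log beta, a, log b)``.

Conditional on the hyperparameters the posterior over weights is the usual
conjugate Gaussian,

    A = alpha I + beta X^T X,   m = beta A^{-1} X^T g(y),   Sigma = A^{-1},

and the predictive distribution at a new row ``x`` is Gaussian *on the
warped scale* with mean ``x.m`` and variance ``x.Sigma.x + 1/beta``.
Deviation (z) scores, centile curves and predictive densities on the
original scale follow by inverting the warp.

Usage follows the statsmodels convention::

    model = WarpedBLR(y, X, column_names=cols, continuous_cols=[0, 1])
    res = model.fit()            # WarpedBLRResults
    z = res.deviation_scores(X_new, y_new)
    print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .shash import shash_inverse, shash_log_deriv, shash_warp

__all__ = [
    "WarpedBLR",
    "WarpedBLRResults",
    "neg_log_evidence",
    "blr_posterior",
]

_PENALTY = 1e10  # returned for non-finite objectives to keep Powell in bounds


def blr_posterior(X: np.ndarray, g: np.ndarray, alpha: float, beta: float):
    """Conjugate posterior (m, Sigma, cho_A) of a Gaussian BLR on response g."""
    d = X.shape[1]
    A = alpha * np.eye(d) + beta * (X.T @ X)
    cho = linalg.cho_factor(A, lower=True)
    m = linalg.cho_solve(cho, beta * (X.T @ g))
    Sigma = linalg.cho_solve(cho, np.eye(d))
    return m, Sigma, cho


def _log_evidence_gaussian(X, g, alpha, beta):
    """Log marginal likelihood of the Gaussian BLR (no warp Jacobian)."""
    n, d = X.shape
    m, _, cho = blr_posterior(X, g, alpha, beta)
    resid = g - X @ m
    logdet_A = 2.0 * np.sum(np.log(np.diag(cho[0])))
    return 0.5 * (
        d * np.log(alpha)
        + n * np.log(beta)
        - beta * (resid @ resid)
        - alpha * (m @ m)
        - logdet_A
        - n * np.log(2.0 * np.pi)
    )


def neg_log_evidence(theta, X: np.ndarray, y: np.ndarray) -> float:
    """Negative log evidence of the warped BLR at ``theta``.

    Parameters
    ----------
    theta : sequence of 4 floats
        ``(log alpha, log beta, a, log b)``.
    X : (n, d) design matrix.
    y : (n,) response on the scale the warp is applied to.

    The objective is ``-[log evidence of the Gaussian BLR on g(y; a, b)]
    - sum_i log g'(y_i)``. Non-finite values are replaced by a large
    penalty so a direction-set optimizer never leaves the feasible region.
    """
    log_alpha, log_beta, a, log_b = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite([log_alpha, log_beta, a, log_b])):
        return _PENALTY
    # keep exp() away from float extremes; exp(50) ~ 5e21 is already an
    # effectively infinite precision / zero-weight regime
    if max(abs(log_alpha), abs(log_beta), abs(log_b)) > 50 or abs(a) > 10:
        return _PENALTY
    alpha, beta, b = np.exp(log_alpha), np.exp(log_beta), np.exp(log_b)
    try:
        g = shash_warp(y, a, b)
        le = _log_evidence_gaussian(X, g, alpha, beta)
        jac = np.sum(shash_log_deriv(y, a, b))
        nle = -(le + jac)
    except (linalg.LinAlgError, FloatingPointError, ValueError):
        return _PENALTY
    if not np.isfinite(nle):
        return _PENALTY
    return float(nle)


def _standardize(arr, mean, sd):
    return (arr - mean) / sd


class WarpedBLR:
    """Warped Bayesian linear regression model.

    Parameters
    ----------
    endog : (n,) array
        Response in original units (e.g. cortical thickness in mm).
    exog : (n, d) array
        Design matrix. Site indicator (one-hot) columns should be left
        as 0/1; continuous columns may be standardized by training
        statistics via ``continuous_cols``.
    column_names : optional list of d column labels.
    continuous_cols : indices of exog columns standardized by training
        mean/SD before fitting (one-hot columns are left untouched).
    standardize_response : standardize endog by its training mean/SD
        before warping (default True); the warp then acts on a
        unit-scale response, keeping (a, b) comparable across regions.
    fix_warp : if True the warp is pinned to the identity (a=0, b=1) and
        only (alpha, beta) are optimized — plain Bayesian ridge.
    """

    def __init__(
        self,
        endog,
        exog,
        column_names=None,
        continuous_cols=None,
        standardize_response: bool = True,
        fix_warp: bool = False,
    ):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[0] != y.shape[0]:
            raise ValueError("endog and exog have incompatible shapes")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in endog/exog")
        if np.var(y) == 0:
            raise ValueError("response is constant; cannot fit a normative model")
        self.endog = y
        self.exog = X
        self.nobs, self.k_exog = X.shape
        self.column_names = (
            list(column_names)
            if column_names is not None
            else [f"x{j}" for j in range(self.k_exog)]
        )
        self.continuous_cols = sorted(continuous_cols) if continuous_cols else []
        self.standardize_response = standardize_response
        self.fix_warp = fix_warp

    def fit(self, xtol: float = 1e-6, ftol: float = 1e-6, maxiter: int = 500):
        """Optimize hyperparameters by Powell and return :class:`WarpedBLRResults`."""
        y, X = self.endog, self.exog.copy()
        if self.standardize_response:
            y_mean, y_sd = float(np.mean(y)), float(np.std(y, ddof=0))
        else:
            y_mean, y_sd = 0.0, 1.0
        ys = _standardize(y, y_mean, y_sd)

        x_mean = np.zeros(self.k_exog)
        x_sd = np.ones(self.k_exog)
        for j in self.continuous_cols:
            mu, sd = float(np.mean(X[:, j])), float(np.std(X[:, j], ddof=0))
            if sd == 0:
                sd = 1.0
            x_mean[j], x_sd[j] = mu, sd
            X[:, j] = (X[:, j] - mu) / sd

        # init: alpha=1, beta = 1/var(g(y)) at the identity warp, a=0, log b=0
        beta0 = 1.0 / float(np.var(ys))

        if self.fix_warp:
            def obj(th2):
                return neg_log_evidence([th2[0], th2[1], 0.0, 0.0], X, ys)

            theta0 = np.array([0.0, np.log(beta0)])
        else:
            def obj(th):
                return neg_log_evidence(th, X, ys)

            theta0 = np.array([0.0, np.log(beta0), 0.0, 0.0])

        opt = optimize.minimize(
            obj,
            theta0,
            method="Powell",
            options={"xtol": xtol, "ftol": ftol, "maxiter": maxiter},
        )
        if self.fix_warp:
            log_alpha, log_beta = opt.x
            a, log_b = 0.0, 0.0
        else:
            log_alpha, log_beta, a, log_b = opt.x
        alpha, beta, b = float(np.exp(log_alpha)), float(np.exp(log_beta)), float(np.exp(log_b))
        g = shash_warp(ys, a, b)
        m, Sigma, _ = blr_posterior(X, g, alpha, beta)
        return WarpedBLRResults(
            model=self,
            alpha=alpha,
            beta=beta,
            a=float(a),
            b=b,
            coef=m,
            coef_cov=Sigma,
            y_mean=y_mean,
            y_sd=y_sd,
            x_mean=x_mean,
            x_sd=x_sd,
            trivial_mean=float(np.mean(y)),
            trivial_var=float(np.var(y, ddof=1)),
            converged=bool(opt.success),
            neg_log_evidence_=float(opt.fun),
            n_train=self.nobs,
        )


@dataclass
class WarpedBLRResults:
    """Fitted warped BLR: hyperparameters, posterior, and prediction methods."""

    alpha: float
    beta: float
    a: float
    b: float
    coef: np.ndarray          # posterior mean m (warped/standardized scale)
    coef_cov: np.ndarray      # posterior covariance Sigma = A^{-1}
    y_mean: float
    y_sd: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    trivial_mean: float       # training response mean (original units)
    trivial_var: float        # training response variance, ddof=1
    converged: bool
    neg_log_evidence_: float
    n_train: int
    model: WarpedBLR | None = None
    column_names: list = field(default_factory=list)

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        self.coef_cov = np.asarray(self.coef_cov, dtype=float)
        self.x_mean = np.asarray(self.x_mean, dtype=float)
        self.x_sd = np.asarray(self.x_sd, dtype=float)
        if self.model is not None and not self.column_names:
            self.column_names = list(self.model.column_names)
        if self.b <= 0:
            raise ValueError("warp shape b must be positive")

    # -- core predictive machinery ------------------------------------
    def _transform_exog(self, exog):
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[1] != self.coef.shape[0]:
            raise ValueError(
                f"design has {X.shape[1]} columns, model expects {self.coef.shape[0]}"
            )
        return (X - self.x_mean) / self.x_sd

    def predictive_moments(self, exog):
        """Predictive mean and SD on the warped/standardized scale, per row."""
        X = self._transform_exog(exog)
        mu_w = X @ self.coef
        var_w = np.einsum("ij,jk,ik->i", X, self.coef_cov, X) + 1.0 / self.beta
        return mu_w, np.sqrt(var_w)

    def deviation_scores(self, exog, endog):
        """z-scores: warped standardized observations against the predictive Gaussian."""
        y = np.asarray(endog, dtype=float).ravel()
        mu_w, s_w = self.predictive_moments(exog)
        g = shash_warp((y - self.y_mean) / self.y_sd, self.a, self.b)
        return (g - mu_w) / s_w

    def predict(self, exog):
        """Median prediction in original units (warp inverse of the predictive mean)."""
        mu_w, _ = self.predictive_moments(exog)
        return self.y_mean + self.y_sd * shash_inverse(mu_w, self.a, self.b)

    def centiles(self, exog, quantiles):
        """Centile curves in original units; shape (n_rows, n_quantiles).

        ``quantiles`` are probabilities in (0, 1); columns are strictly
        increasing in the quantile.
        """
        q = np.asarray(quantiles, dtype=float).ravel()
        if np.any(q <= 0) or np.any(q >= 1):
            raise ValueError("quantiles must lie strictly inside (0, 1)")
        mu_w, s_w = self.predictive_moments(exog)
        zq = stats.norm.ppf(q)
        warped = mu_w[:, None] + s_w[:, None] * zq[None, :]
        return self.y_mean + self.y_sd * shash_inverse(warped, self.a, self.b)

    def log_density(self, exog, endog):
        """Predictive log-density of observations in original units (per row)."""
        y = np.asarray(endog, dtype=float).ravel()
        mu_w, s_w = self.predictive_moments(exog)
        ys = (y - self.y_mean) / self.y_sd
        g = shash_warp(ys, self.a, self.b)
        lp = stats.norm.logpdf(g, loc=mu_w, scale=s_w)
        return lp + shash_log_deriv(ys, self.a, self.b) - np.log(self.y_sd)

    def trivial_log_density(self, endog):
        """Log-density under the trivial Gaussian with training mean/variance."""
        y = np.asarray(endog, dtype=float).ravel()
        return stats.norm.logpdf(
            y, loc=self.trivial_mean, scale=np.sqrt(self.trivial_var)
        )

    # -- reporting / serialization ------------------------------------
    def summary(self) -> str:
        lines = [
            "Warped Bayesian Linear Regression Results",
            "=" * 57,
            f"{'No. observations:':<25}{self.n_train:>10d}",
            f"{'Converged:':<25}{str(self.converged):>10}",
            f"{'Neg. log evidence:':<25}{self.neg_log_evidence_:>12.4f}",
            f"{'alpha (prior prec.):':<25}{self.alpha:>12.5g}",
            f"{'beta (noise prec.):':<25}{self.beta:>12.5g}",
            f"{'warp skew a:':<25}{self.a:>12.5g}",
            f"{'warp shape b:':<25}{self.b:>12.5g}",
            "-" * 57,
            f"{'coef':<20}{'post. mean':>15}{'post. sd':>15}",
        ]
        sds = np.sqrt(np.diag(self.coef_cov))
        names = self.column_names or [f"x{j}" for j in range(len(self.coef))]
        for name, c, s in zip(names, self.coef, sds):
            lines.append(f"{name:<20}{c:>15.6g}{s:>15.6g}")
        lines.append("=" * 57)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "a": self.a,
            "b": self.b,
            "coef": self.coef.tolist(),
            "coef_cov": self.coef_cov.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "trivial_mean": self.trivial_mean,
            "trivial_var": self.trivial_var,
            "converged": self.converged,
            "neg_log_evidence": self.neg_log_evidence_,
            "n_train": self.n_train,
            "column_names": list(self.column_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WarpedBLRResults":
        return cls(
            alpha=d["alpha"],
            beta=d["beta"],
            a=d["a"],
            b=d["b"],
            coef=np.asarray(d["coef"]),
            coef_cov=np.asarray(d["coef_cov"]),
            y_mean=d["y_mean"],
            y_sd=d["y_sd"],
            x_mean=np.asarray(d["x_mean"]),
            x_sd=np.asarray(d["x_sd"]),
            trivial_mean=d["trivial_mean"],
            trivial_var=d["trivial_var"],
            converged=d["converged"],
            neg_log_evidence_=d["neg_log_evidence"],
            n_train=d["n_train"],
            column_names=list(d.get("column_names", [])),
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load_json(cls, path) -> "WarpedBLRResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
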