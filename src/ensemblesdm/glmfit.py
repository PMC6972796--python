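"""Fast binomial-logit GLM fitting by iteratively reweighted least squares.

The stability-selection stage runs tens of thousands of small logistic
fits (bivariate screens and stepwise-AIC searches over resampled
absence sets), so the fitter is a thin NumPy IRLS loop rather than a
full GLM framework.  Results (coefficients, log-likelihood, AIC,
deviances) are validated against statsmodels in the test suite.

Separation is handled by an automatic ridge-stabilized refit, flagged
on the result, so envelope-style perfectly separable toy data never
crash the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LOGEPS = 1e-12


@dataclass
class LogisticFit:
    """Fitted binomial-logit GLM.

    ``coef`` holds the intercept first, then one coefficient per
    column of the design matrix.  ``stabilized`` is True when the fit
    required a ridge penalty to converge (quasi-separation); the
    reported log-likelihood and AIC are those of the penalized
    coefficients evaluated under the unpenalized likelihood.
    """

    coef: np.ndarray
    loglik: float
    deviance: float
    null_deviance: float
    aic: float
    n_params: int
    converged: bool
    stabilized: bool
    cov: np.ndarray | None = None

    @property
    def d_squared(self) -> float:
        """Explained deviance D^2 = 1 - residual/null deviance.

        For a binary-response logistic model the saturated
        log-likelihood is zero, so D^2 coincides with McFadden's
        pseudo-R^2, 1 - l/l0.
        """
        if self.null_deviance == 0:
            return 0.0
        return 1.0 - self.deviance / self.null_deviance

    @property
    def bse(self) -> np.ndarray:
        if self.cov is None:
            raise ValueError("covariance not available")
        return np.sqrt(np.diag(self.cov))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        eta = self.coef[0] + X @ self.coef[1:]
        return expit(eta)


def expit(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def _bernoulli_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, _LOGEPS, 1 - _LOGEPS)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))


def null_loglik(y: np.ndarray) -> float:
    p = y.mean()
    if p <= 0 or p >= 1:
        return 0.0
    n = len(y)
    k = y.sum()
    return float(k * np.log(p) + (n - k) * np.log1p(-p))


def _irls(Xd: np.ndarray, y: np.ndarray, ridge: float,
          max_iter: int, tol: float):
    n, p = Xd.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    pen = ridge * np.eye(p)
    pen[0, 0] = 0.0  # never penalize the intercept
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        # penalized Newton step on the working response
        XtW = Xd.T * w
        H = XtW @ Xd + pen
        g = Xd.T @ (y - mu) - pen @ beta
        try:
            beta = beta + np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, False, None
        ll = _bernoulli_loglik(y, expit(Xd @ beta)) \
            - 0.5 * ridge * float(beta[1:] @ beta[1:])
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll
    eta = Xd @ beta
    mu = expit(eta)
    w = mu * (1 - mu)
    H = (Xd.T * w) @ Xd + pen
    return beta, converged, H


def fit_logistic(X: np.ndarray, y: np.ndarray, *,
                 max_iter: int = 60, tol: float = 1e-10,
                 ridge_fallback: float = 1e-3,
                 want_cov: bool = False) -> LogisticFit:
    """Fit y ~ intercept + X by maximum likelihood.

    X may have zero columns (intercept-only model).  If the
    unpenalized fit diverges (complete or quasi separation), the model
    is refit with a small ridge penalty on the slopes and flagged via
    ``stabilized``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        X = X.T
    n = len(y)
    Xd = np.column_stack([np.ones(n), X]) if X.shape[1] else np.ones((n, 1))
    p = Xd.shape[1]

    beta, converged, H = _irls(Xd, y, 0.0, max_iter, tol)
    stabilized = False
    # diverging slopes or a singular Hessian signal separation
    if not converged or not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 30:
        beta, converged, H = _irls(Xd, y, ridge_fallback, max_iter, tol)
        stabilized = True

    mu = expit(Xd @ beta)
    ll = _bernoulli_loglik(y, mu)
    ll0 = null_loglik(y)
    deviance = -2.0 * ll
    null_dev = -2.0 * ll0
    cov = None
    if want_cov and H is not None:
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = None
    return LogisticFit(coef=beta, loglik=ll, deviance=deviance,
                       null_deviance=null_dev, aic=-2.0 * ll + 2.0 * p,
                       n_params=p, converged=converged,
                       stabilized=stabilized, cov=cov)
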