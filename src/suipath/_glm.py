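"""Minimal Newton–Raphson logistic regression used by the matching and
regression stages.  Wald inference from the inverse observed information."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm


class SeparationError(ValueError):
    """The likelihood is unbounded: some covariate separates the outcome."""


@dataclass
class LogisticResult:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coef / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.z))

    def ci95(self) -> np.ndarray:
        return np.column_stack([self.coef - 1.96 * self.se, self.coef + 1.96 * self.se])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.coef)


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    tol: float = 1e-8,
    max_iter: int = 100,
    raise_on_separation: bool = True,
) -> LogisticResult:
    """Newton–Raphson MLE with step-halving.

    Separation is flagged when fitted probabilities collapse onto {0, 1}
    for every observation while coefficients diverge.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        W = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving on the log-likelihood
        ll_new = None
        for _ in range(30):
            cand = beta + step
            eta_c = X @ cand
            ll_c = float(np.sum(y * eta_c - np.logaddexp(0.0, eta_c)))
            if ll_c >= ll_old - 1e-12 or not np.isfinite(ll_old):
                ll_new, beta = ll_c, cand
                break
            step *= 0.5
        if ll_new is None:
            break
        if abs(ll_new - ll_old) < tol and np.max(np.abs(grad)) < 1e-4:
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new

    eta = X @ beta
    mu = expit(eta)
    # perfect separation: every observation fitted (numerically) exactly to
    # its label while coefficients diverge
    separated = bool(np.all(np.abs(mu - y) < 1e-6)) and np.max(np.abs(beta)) > 10
    if separated and raise_on_separation:
        raise SeparationError(
            "perfect separation detected: remove the separating covariate(s) and refit"
        )
    W = mu * (1.0 - mu)
    H = (X * W[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return LogisticResult(
        names=list(names), coef=beta, se=se, cov=cov, loglik=float(ll_old),
        converged=converged, n_iter=it,
    )
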