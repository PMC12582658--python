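"""Weighted logistic regression by Newton-Raphson.

Maximizes the weighted Bernoulli log-likelihood
``sum_i w_i [y_i log p_i + (1 - y_i) log(1 - p_i)]`` with
``p = expit(X beta)``. Weights may be non-integer (inverse-probability
weights); the score and Hessian are the usual weighted forms.

This fitter is deliberately self-contained: it reports convergence (max
absolute score below tolerance), iteration count, and a separation flag,
and it never silently returns a non-converged fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LogitFit:
    coef: np.ndarray
    converged: bool
    n_iter: int
    max_score: float
    separation_suspected: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.coef)


def expit(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _loglik(y: np.ndarray, w: np.ndarray, eta: np.ndarray) -> float:
    # stable: log(1 + exp(eta)) via logaddexp
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def newton_logistic(X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None,
                    *, tol: float = 1e-8, max_iter: int = 100,
                    ridge: float = 0.0) -> LogitFit:
    """Fit a weighted logistic regression; raise nothing, flag everything.

    ``tol`` is on the max absolute component of the score vector. After
    the score criterion is met one further Newton step is taken, so the
    returned coefficients are accurate to roughly the square of the
    score-implied error (Newton converges quadratically near the optimum).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    # unit-RMS column scaling: conditions the Hessian without changing the
    # fitted model (coefficients are unscaled on return); the tolerance
    # applies to the score of the *scaled* problem
    scale = np.sqrt(np.mean(X**2, axis=0))
    scale[scale == 0] = 1.0
    Xs = X / scale
    beta = np.zeros(p)
    eta = Xs @ beta
    ll = _loglik(y, w, eta)
    converged = False
    it = 0
    max_score = np.inf
    hit_tol = False
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        score = Xs.T @ (w * (y - mu))
        max_score = float(np.max(np.abs(score)))
        if max_score < tol:
            if hit_tol:
                converged = True
                break
            hit_tol = True  # one polishing step past the tolerance
        wvar = w * mu * (1.0 - mu)
        H = Xs.T @ (Xs * wvar[:, None])
        if ridge > 0:
            H = H + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(p), score)
        # step-halving to guarantee likelihood ascent
        improved = False
        for _ in range(50):
            eta_new = Xs @ (beta + step)
            ll_new = _loglik(y, w, eta_new)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                improved = True
                break
            step = step / 2.0
        if not improved:
            break  # stalled: report non-convergence rather than garbage
        beta = beta + step
        eta = Xs @ beta
        ll = ll_new
    else:
        mu = expit(eta)
        max_score = float(np.max(np.abs(Xs.T @ (w * (y - mu)))))
        converged = max_score < tol
    separation = bool(np.max(np.abs(beta / scale)) > 30.0)
    return LogitFit(beta / scale, converged, it, max_score, separation)
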