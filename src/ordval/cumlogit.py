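"""Cumulative-logit (proportional-odds) likelihood engine.

Model: P(Y <= k | x) = expit(theta_k - x @ beta) for k = 1..K-1 with
strictly ascending thresholds theta and one slope vector shared across
category cuts (the parallel / proportional-odds form). Category
probabilities are differences of adjacent cumulative probabilities.

One optimizer serves both the unpenalized fit and the ridge fit: the
objective is the negative log-likelihood plus lam * ||beta_std||^2, with
the penalty taken on internally standardized columns and intercepts left
unpenalized. Thresholds are optimized through an ascending
reparameterization theta_k = theta_1 + sum(exp(gaps)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

_EPS = 1e-12
MAX_ITER = 500
GTOL = 1e-8
# |standardized slope| above this is treated as separation/divergence
_BETA_DIVERGED = 30.0


class ConvergenceError(RuntimeError):
    """Optimizer failed, or slopes diverged (e.g., complete separation)."""


@dataclass
class CumLogitFit:
    """Fitted parallel cumulative-logit model on the original column scale."""

    thetas: np.ndarray  # (K-1,) ascending
    beta: np.ndarray  # (p,)
    loglik: float
    K: int
    lam: float = 0.0
    converged: bool = True
    n_iter: int = 0

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        eta = X @ self.beta if X.shape[1] else np.zeros(X.shape[0])
        cum = expit(self.thetas[None, :] - eta[:, None])  # (n, K-1)
        probs = np.diff(
            np.concatenate(
                [np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))], axis=1
            ),
            axis=1,
        )
        return np.clip(probs, 0.0, 1.0)


def _unpack(params: np.ndarray, K: int):
    t1 = params[0]
    gaps = np.exp(params[1 : K - 1])
    thetas = t1 + np.concatenate([[0.0], np.cumsum(gaps)])
    beta = params[K - 1 :]
    return thetas, gaps, beta


def _nll_grad(params: np.ndarray, X: np.ndarray, y: np.ndarray, K: int, lam: float):
    n, p = X.shape
    thetas, gaps, beta = _unpack(params, K)
    eta = X @ beta if p else np.zeros(n)
    z = thetas[None, :] - eta[:, None]  # (n, K-1)
    s = expit(z)
    sp = s * (1.0 - s)  # derivative of expit at z
    # per-row probability of the observed category
    c = np.concatenate([np.zeros((n, 1)), s, np.ones((n, 1))], axis=1)
    prob = c[np.arange(n), y] - c[np.arange(n), y - 1]
    prob = np.clip(prob, _EPS, None)
    nll = -np.sum(np.log(prob)) + lam * float(beta @ beta)

    inv = 1.0 / prob
    # d prob / d theta_k = sp_k if k == y, -sp_k if k == y-1 (1-based cuts)
    g_theta = np.zeros(K - 1)
    upper = y <= K - 1  # s_y exists
    lower = y >= 2  # s_{y-1} exists
    np.add.at(g_theta, y[upper] - 1, -inv[upper] * sp[np.arange(n)[upper], y[upper] - 1])
    np.add.at(g_theta, y[lower] - 2, inv[lower] * sp[np.arange(n)[lower], y[lower] - 2])
    # chain to (t1, log-gaps): theta_k depends on gap_j for k-1 >= j
    g_t1 = g_theta.sum()
    g_gap = np.array(
        [g_theta[j + 1 :].sum() * gaps[j] for j in range(K - 2)], dtype=float
    )
    if p:
        # dp/dbeta = (-sp_y + sp_{y-1}) * x, so d(-log p)/dbeta = (1/p)(sp_y - sp_{y-1}) x
        w = np.zeros(n)
        w[upper] += sp[np.arange(n)[upper], y[upper] - 1]
        w[lower] -= sp[np.arange(n)[lower], y[lower] - 2]
        g_beta = X.T @ (inv * w) + 2.0 * lam * beta
    else:
        g_beta = np.zeros(0)
    grad = np.concatenate([[g_t1], g_gap, g_beta])
    return nll, grad


def _start_params(y: np.ndarray, K: int, p: int) -> np.ndarray:
    freq = np.bincount(y, minlength=K + 1)[1:] / len(y)
    cum = np.clip(np.cumsum(freq)[:-1], 1e-6, 1 - 1e-6)
    thetas = logit(cum)
    gaps = np.diff(thetas)
    gaps = np.maximum(gaps, 1e-3)
    return np.concatenate([[thetas[0]], np.log(gaps), np.zeros(p)])


def fit_cumlogit(
    X: np.ndarray,
    y: np.ndarray,
    K: int = 3,
    lam: float = 0.0,
    standardize_penalty: bool = True,
) -> CumLogitFit:
    """Maximize the (optionally ridge-penalized) cumulative-logit likelihood.

    ``y`` holds integer category ranks 1..K; all K categories must be
    present. Columns are standardized internally (the penalty, when active,
    applies on the standardized scale) and estimates are mapped back to the
    original scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be (n, p) aligned with y")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    counts = np.bincount(y, minlength=K + 1)[1:]
    if np.any(counts == 0):
        missing = [k + 1 for k in range(K) if counts[k] == 0]
        raise ValueError(f"outcome categories {missing} absent from y")
    n, p = X.shape
    if p:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant column in design matrix")
        Xs = (X - mu) / sd
    else:
        Xs = X
    x0 = _start_params(y, K, p)
    res = minimize(
        _nll_grad,
        x0,
        args=(Xs, y, K, lam),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": MAX_ITER, "gtol": GTOL, "ftol": 1e-12},
    )
    thetas_s, _, beta_s = _unpack(res.x, K)
    if not res.success and np.linalg.norm(res.jac) > 1e-3 * max(1.0, n / 100):
        raise ConvergenceError(f"cumulative-logit fit did not converge: {res.message}")
    if p and np.max(np.abs(beta_s)) > _BETA_DIVERGED:
        raise ConvergenceError(
            "slope estimates diverged; possible complete separation"
        )
    if p:
        beta = beta_s / sd
        thetas = thetas_s + float(beta_s @ (mu / sd))
    else:
        beta = beta_s
        thetas = thetas_s
    # loglik excludes the penalty term
    nll_unpen, _ = _nll_grad(res.x, Xs, y, K, 0.0)
    return CumLogitFit(
        thetas=thetas,
        beta=beta,
        loglik=-float(nll_unpen),
        K=K,
        lam=lam,
        converged=bool(res.success),
        n_iter=int(res.nit),
    )


def heldout_loglik(fit: CumLogitFit, X: np.ndarray, y: np.ndarray) -> float:
    """Sum of log predicted probabilities of the observed categories."""
    probs = fit.predict_proba(np.asarray(X, dtype=float))
    p_obs = probs[np.arange(len(y)), np.asarray(y, dtype=int) - 1]
    return float(np.sum(np.log(np.clip(p_obs, _EPS, None))))
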