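"""Vectorized Newton–Raphson probit maximum likelihood.

The placement-value indicator regression refits the same moderately sized
probit model thousands of times inside bootstrap and simulation loops, so the
solver is a tight numpy Newton iteration with step halving rather than a
general GLM framework.  Agreement with ``statsmodels`` GLM (probit link) is
pinned to <1e-6 in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = [
    "ProbitResult",
    "QuasiSeparationWarning",
    "FitConvergenceError",
    "fit_probit",
]

# probability clip keeps the working weights finite near separation
_P_EPS = 1e-12
# |linear predictor| beyond which the response is numerically deterministic
_ETA_SEPARATION = 8.0


class QuasiSeparationWarning(UserWarning):
    """The likelihood is flat/unbounded: fitted probabilities hit 0 or 1."""


class FitConvergenceError(RuntimeError):
    """Newton iteration did not converge; carries the last iterate."""

    def __init__(self, message: str, last_beta: np.ndarray):
        super().__init__(message)
        self.last_beta = last_beta


@dataclass
class ProbitResult:
    params: np.ndarray
    cov: np.ndarray          # inverse Fisher information (naive, see caller)
    converged: bool
    n_iter: int
    loglike: float
    separation: bool


_SQRT2PI = np.sqrt(2.0 * np.pi)


def _npdf(eta: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * eta * eta) / _SQRT2PI


def _loglike(eta: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(ndtr(eta), _P_EPS, 1.0 - _P_EPS)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def fit_probit(
    X: np.ndarray,
    y: np.ndarray,
    *,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> ProbitResult:
    """Fit P(y=1) = Phi(X beta) by Newton–Raphson with step halving.

    Parameters
    ----------
    X : (n, p) design matrix including the intercept column.
    y : (n,) binary response in {0, 1}.

    Raises
    ------
    FitConvergenceError
        If the iteration cap is reached without separation being the cause.

    Warns
    -----
    QuasiSeparationWarning
        When the response is degenerate (all 0 / all 1) or fitted linear
        predictors run off to the deterministic region; the last iterate is
        returned with ``converged=False``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"response length {y.shape} does not match design {X.shape}")

    degenerate = bool(y.min() == y.max())
    if degenerate:
        warnings.warn(
            "degenerate response (all indicators equal): probit likelihood "
            "is unbounded; returning last iterate",
            QuasiSeparationWarning,
            stacklevel=2,
        )

    beta = np.zeros(p)
    eta = X @ beta
    ll = _loglike(eta, y)
    separation = degenerate
    converged = False
    it = 0

    for it in range(1, max_iter + 1):
        prob = np.clip(ndtr(eta), _P_EPS, 1.0 - _P_EPS)
        dens = _npdf(eta)
        v = prob * (1.0 - prob)
        score = X.T @ ((y - prob) * dens / v)
        w = dens * dens / v
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            separation = True
            break

        # step-halving line search: never accept a likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_cand = _loglike(X @ cand, y)
            if ll_cand >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        eta = X @ beta
        ll_new = _loglike(eta, y)

        if np.max(np.abs(scale * step)) < tol:
            converged = True
            ll = ll_new
            break
        ll = ll_new

        if np.max(np.abs(eta)) > _ETA_SEPARATION and not degenerate:
            # fitted probabilities numerically 0/1 for some observations;
            # keep iterating only if the step is still productive
            if np.max(np.abs(step)) > 1.0:
                separation = True
                break

    if separation and not degenerate:
        warnings.warn(
            "quasi-complete separation detected in indicator probit fit; "
            "coefficients from last stable iterate",
            QuasiSeparationWarning,
            stacklevel=2,
        )
    if not converged and not separation:
        raise FitConvergenceError(
            f"probit Newton iteration failed to converge in {max_iter} steps",
            last_beta=beta,
        )

    prob = np.clip(ndtr(eta), _P_EPS, 1.0 - _P_EPS)
    dens = _npdf(eta)
    w = dens * dens / (prob * (1.0 - prob))
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)

    return ProbitResult(
        params=beta,
        cov=cov,
        converged=converged,
        n_iter=it,
        loglike=ll,
        separation=separation,
    )
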