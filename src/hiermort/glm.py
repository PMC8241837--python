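"""Poisson log-likelihood and an IRLS fitter for episode tables.

The fitter is deliberately small: it exists to initialise the MCMC sampler
at the non-hierarchical maximum-likelihood estimate, to provide the
episode-split Poisson MLE used in the Cox-equivalence checks, and to expose
a per-iteration deviance trace.  Step halving guarantees the deviance is
non-increasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["poisson_loglik", "poisson_deviance", "poisson_irls",
           "IRLSResult", "NonConvergenceError"]


class NonConvergenceError(RuntimeError):
    pass


def poisson_loglik(eta, d) -> float:
    """Sum over episodes of d*log(mu) - mu - log(d!), with log(mu) = eta.

    For the 0/1 episode indicators log(d!) vanishes identically.
    """
    eta = np.asarray(eta, dtype=float)
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    return float(d @ eta - np.exp(eta).sum())


def poisson_deviance(d, mu) -> float:
    """Residual deviance 2*sum(d*log(d/mu) - (d - mu)) with 0*log(0) = 0."""
    d = np.asarray(d, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(d > 0, d * np.log(d / mu), 0.0)
    return float(2.0 * (term - (d - mu)).sum())


@dataclass
class IRLSResult:
    coef: np.ndarray
    cov: np.ndarray                # inverse Fisher information at the MLE
    deviance_trace: list[float]    # deviance after each iteration
    n_iter: int
    converged: bool
    names: tuple[str, ...] | None = None

    def coef_named(self) -> dict[str, float]:
        names = self.names or tuple(f"x{i}" for i in range(len(self.coef)))
        return dict(zip(names, map(float, self.coef)))


def poisson_irls(X, d, offset, names=None, max_iter: int = 100,
                 tol: float = 1e-8, ridge: float = 0.0) -> IRLSResult:
    """Fit a Poisson GLM with log link and fixed offset by IRLS.

    Convergence is declared when the score max-norm falls below ``tol``.
    ``ridge`` adds a tiny L2 penalty, used only to stabilise saturated
    baselines whose MLE lies at infinity.
    """
    X = np.asarray(X, dtype=float)
    d = np.asarray(d, dtype=float)
    offset = np.asarray(offset, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta + offset
    mu = np.exp(eta)
    dev = poisson_deviance(d, mu) + ridge * beta @ beta
    trace = []
    converged = False
    grad_norm = np.inf
    for it in range(1, max_iter + 1):
        W = mu
        z = (eta - offset) + (d - mu) / mu
        A = (X.T * W) @ X
        if ridge > 0:
            A = A + ridge * np.eye(p)
        rhs = (X.T * W) @ z
        try:
            beta_new = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:
            raise NonConvergenceError(f"singular information matrix: {exc}") from exc
        # step-halve towards the previous iterate until the deviance drops
        step = beta_new - beta
        for _ in range(40):
            cand = beta + step
            eta_c = X @ cand + offset
            mu_c = np.exp(eta_c)
            dev_c = poisson_deviance(d, mu_c) + ridge * cand @ cand
            if np.isfinite(dev_c) and dev_c <= dev + 1e-12:
                break
            step *= 0.5
        beta, eta, mu, dev = cand, eta_c, mu_c, dev_c
        trace.append(dev)
        grad = X.T @ (d - mu) - ridge * beta
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm < tol:
            converged = True
            break
    if not converged:
        raise NonConvergenceError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(score max-norm {grad_norm:.3e})"
        )
    W = mu
    A = (X.T * W) @ X
    if ridge > 0:
        A = A + ridge * np.eye(p)
    cov = np.linalg.inv(A)
    return IRLSResult(coef=beta, cov=cov, deviance_trace=trace, n_iter=it,
                      converged=converged,
                      names=tuple(names) if names is not None else None)
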