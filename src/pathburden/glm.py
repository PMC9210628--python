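"""Logistic regression by iteratively reweighted least squares.

Deliberately small and self-contained: the association layer needs exact
control over convergence, separation/rank diagnostics, and a vectorized
solver that refits the same design against hundreds of permuted outcome
vectors at once (the permutation engines in the global test and the gene
screen are built on it).

Convergence is declared when the largest absolute score component drops
below ``tol`` (default 1e-8), capped at ``max_iter`` iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit


class SeparationError(RuntimeError):
    """Perfect (or quasi-) separation: the MLE does not exist."""


class RankDeficiencyError(ValueError):
    """Design matrix not of full column rank."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with observed-information covariance."""

    params: np.ndarray
    cov: np.ndarray
    n_iter: int
    converged: bool
    loglik: float
    colnames: list[str]

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald_ci(self, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        se = self.bse
        return self.params - z * se, self.params + z * se

    def pvalues(self) -> np.ndarray:
        from scipy.stats import norm

        z = self.params / self.bse
        return 2 * norm.sf(np.abs(z))


def _check_rank(X: np.ndarray, colnames: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved via pivoted QR: unpivoted trailing columns
        _, R, piv = _qr_pivot(X)
        bad = [colnames[j] for j in piv[rank:]]
        raise RankDeficiencyError(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(bad)
        )


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def logistic_fit(
    y: np.ndarray,
    X: np.ndarray,
    colnames: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Fit a logistic regression of binary ``y`` on design ``X`` (with any
    intercept column included by the caller).

    Raises
    ------
    RankDeficiencyError
        if ``X`` is not of full column rank (collinear columns are named).
    SeparationError
        if the likelihood is monotone in some direction (perfect separation);
        the message names the column most aligned with the runaway direction.
    ValueError
        for degenerate outcomes (all 0 or all 1) or n <= p.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if colnames is None:
        colnames = [f"x{j}" for j in range(p)]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("degenerate outcome: all observations in one class")
    if n <= p:
        raise ValueError(f"n={n} must exceed number of parameters p={p}")
    _check_rank(X, colnames)

    beta = np.zeros(p)
    converged = False
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        if np.max(np.abs(eta)) > 30 and np.min(w) < 1e-12:
            _raise_separation(X, y, mu, beta, colnames)
        XtWX = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            _raise_separation(X, y, mu, beta, colnames)
        # step-halving if the step overshoots the likelihood
        ll_old = _loglik(y, eta)
        new_beta = beta + step
        for _ in range(8):
            if _loglik(y, X @ new_beta) >= ll_old - 1e-12:
                break
            step = step / 2.0
            new_beta = beta + step
        beta = new_beta
        it_used = it
    else:
        it_used = max_iter
    if converged:
        it_used = it

    eta = X @ beta
    mu = expit(eta)
    if not converged:
        _raise_separation(X, y, mu, beta, colnames)
    # the score also vanishes when the likelihood saturates along a
    # separating direction: catch that case explicitly
    if (
        mu[y == 1].min(initial=1.0) > 1 - 1e-6
        and mu[y == 0].max(initial=0.0) < 1e-6
    ):
        _raise_separation(X, y, mu, beta, colnames)
    w = mu * (1.0 - mu)
    XtWX = (X * w[:, None]).T @ X
    cov = np.linalg.inv(XtWX)
    return LogisticFit(
        params=beta,
        cov=cov,
        n_iter=it_used,
        converged=converged,
        loglik=_loglik(y, eta),
        colnames=list(colnames),
    )


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _raise_separation(X, y, mu, beta, colnames):
    fitted_extreme = (mu[y == 1].min(initial=1.0) > 1 - 1e-8) and (
        mu[y == 0].max(initial=0.0) < 1e-8
    )
    scale = np.abs(beta) * X.std(axis=0)
    worst = colnames[int(np.argmax(scale))]
    kind = "perfect separation" if fitted_extreme else "quasi-separation or non-convergence"
    raise SeparationError(
        f"{kind} detected; offending column: {worst!r} "
        f"(|coef x sd| = {scale.max():.3g})"
    )


def batched_logistic_residuals(
    Y: np.ndarray,
    X: np.ndarray,
    beta0: np.ndarray | None = None,
    max_iter: int = 25,
    tol: float = 1e-6,
) -> np.ndarray:
    """Fit logistic regressions of each row of ``Y`` (B x n) on the shared
    design ``X`` (n x p); return response residuals ``Y - mu_hat`` (B x n).

    Vectorized Newton iterations across the B outcome vectors; used by
    permutation tests where the same covariate design is refit against many
    relabelled outcomes.  A warm start ``beta0`` (the unpermuted fit) cuts
    the iteration count roughly in half.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    B, n = Y.shape
    p = X.shape[1]
    beta = np.tile(beta0 if beta0 is not None else np.zeros(p), (B, 1))
    for _ in range(max_iter):
        eta = beta @ X.T  # (B, n)
        mu = expit(eta)
        score = (Y - mu) @ X  # (B, p)
        active = np.max(np.abs(score), axis=1) >= tol
        if not active.any():
            break
        w = mu[active] * (1 - mu[active])  # (Ba, n)
        H = np.einsum("bn,np,nq->bpq", w, X, X, optimize=True)
        H[:, np.arange(p), np.arange(p)] += 1e-10
        step = np.linalg.solve(H, score[active][..., None])[..., 0]
        beta[active] = _damped_update(
            beta[active], step, Y[active], X, eta[active]
        )
    eta = beta @ X.T
    return Y - expit(eta)


def _row_loglik(Y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return (Y * eta).sum(axis=1) - np.logaddexp(0.0, eta).sum(axis=1)


def _damped_update(beta, step, Y, X, eta_old, n_halvings: int = 12):
    """Newton update with per-row step-halving on the log-likelihood.

    Rows whose step never stops decreasing the likelihood are reverted to
    their previous iterate, so divergence cannot be accepted.
    """
    ll_old = _row_loglik(Y, eta_old)
    new = beta + step
    for _ in range(n_halvings):
        worse = _row_loglik(Y, new @ X.T) < ll_old - 1e-10
        if not worse.any():
            break
        step = np.where(worse[:, None], step / 2.0, 0.0)
        new = new - step
    else:
        still = _row_loglik(Y, new @ X.T) < ll_old - 1e-10
        new = np.where(still[:, None], beta, new)
    return new


def batched_logistic_varying_column(
    y: np.ndarray,
    C: np.ndarray,
    G: np.ndarray,
    beta0: np.ndarray | None = None,
    max_iter: int = 25,
    tol: float = 1e-6,
    chunk: int = 256,
) -> np.ndarray:
    """Wald z-statistics for one varying design column across permutations.

    Fits, for each row ``g`` of ``G`` (B x n), the logistic regression of the
    fixed outcome ``y`` on ``[g, C]`` and returns the Wald z of the ``g``
    coefficient (length B).  Processed in chunks to bound memory.
    """
    y = np.asarray(y, dtype=float).ravel()
    C = np.asarray(C, dtype=float)
    G = np.asarray(G, dtype=float)
    B, n = G.shape
    p = C.shape[1] + 1
    out = np.empty(B)
    for s in range(0, B, chunk):
        Gc = G[s : s + chunk]
        b = Gc.shape[0]
        Xb = np.empty((b, n, p))
        Xb[:, :, 0] = Gc
        Xb[:, :, 1:] = C[None, :, :]
        beta = np.tile(beta0 if beta0 is not None else np.zeros(p), (b, 1))
        Yb = np.tile(y, (b, 1))
        for _ in range(max_iter):
            eta = np.einsum("bnp,bp->bn", Xb, beta)
            mu = expit(eta)
            score = np.einsum("bn,bnp->bp", y[None, :] - mu, Xb)
            if np.max(np.abs(score)) < tol:
                break
            w = mu * (1 - mu)
            H = np.einsum("bn,bnp,bnq->bpq", w, Xb, Xb, optimize=True)
            H[:, np.arange(p), np.arange(p)] += 1e-10
            step = np.linalg.solve(H, score[..., None])[..., 0]
            ll_old = _row_loglik(Yb, eta)
            new = beta + step
            for _ in range(12):
                eta_new = np.einsum("bnp,bp->bn", Xb, new)
                worse = _row_loglik(Yb, eta_new) < ll_old - 1e-10
                if not worse.any():
                    break
                step = np.where(worse[:, None], step / 2.0, 0.0)
                new = new - step
            else:
                eta_new = np.einsum("bnp,bp->bn", Xb, new)
                still = _row_loglik(Yb, eta_new) < ll_old - 1e-10
                new = np.where(still[:, None], beta, new)
            beta = new
        eta = np.einsum("bnp,bp->bn", Xb, beta)
        mu = expit(eta)
        w = mu * (1 - mu)
        H = np.einsum("bn,bnp,bnq->bpq", w, Xb, Xb, optimize=True)
        H[:, np.arange(p), np.arange(p)] += 1e-10
        cov00 = np.linalg.inv(H)[:, 0, 0]
        out[s : s + chunk] = beta[:, 0] / np.sqrt(cov00)
    return out
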