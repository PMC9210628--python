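"""Gene-level dual screen and mediation within a pathway.

Two per-gene associations are screened jointly:

1. burden -> expression: OLS of the gene's log2-CPM on the pathway's binary
   any-mutation flag plus covariates;
2. expression -> outcome: logistic regression of case/control status on the
   gene's log2-CPM plus covariates.

Each receives an empirical P-value by permutation of the exposure of
interest (the mutation flag in 1, the gene's expression in 2) with full
refitting per permutation; a gene passes the screen when both empirical
P < 0.05.

For passing genes, the proportion of the burden-outcome association
mediated by the gene is estimated by the difference-of-coefficients method
on the log-odds scale: ``(total - direct) / total`` where ``total`` is the
mutation coefficient without the gene's expression in the model and
``direct`` the same with it.  A percentile bootstrap over samples gives the
CI.  Because the odds ratio is non-collapsible, total and direct + indirect
do not decompose exactly in general, and the proportion may be negative or
exceed one (inconsistent mediation is reported, not suppressed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .glm import (
    batched_logistic_varying_column,
    logistic_fit,
)

logger = logging.getLogger(__name__)


@dataclass
class GeneScreenResult:
    gene: str
    beta_tmb_expr: float
    se_tmb_expr: float
    p_tmb_expr: float
    or_expr_outcome: float
    ci_low: float
    ci_high: float
    p_expr_outcome: float
    passes_screen: bool


@dataclass
class MediationResult:
    gene: str
    total_effect: float
    direct_effect: float
    proportion_mediated: float | None
    ci_low: float | None
    ci_high: float | None
    n_boot: int


def _ols_beta_se(y: np.ndarray, x: np.ndarray, C: np.ndarray):
    """Coefficient of x in OLS of y on [x, C] (C includes intercept)."""
    X = np.column_stack([x, C])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return float(coef[0]), float(np.sqrt(cov[0, 0]))


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each row of M (B x n) on the column space of C."""
    Q, _ = np.linalg.qr(C)
    return M - (M @ Q) @ Q.T


def screen_genes(
    matrix: pd.DataFrame,
    tmb_any,
    outcome,
    covariates,
    pathway_genes,
    n_perm: int = 10_000,
    seed: int = 0,
    use_permutation: bool = True,
    alpha: float = 0.05,
) -> list[GeneScreenResult]:
    """Dual screen of every pathway gene (burden->expression and
    expression->outcome), with empirical permutation P-values.

    ``matrix`` is genes x samples log2 CPM aligned with ``tmb_any`` (binary)
    and ``outcome`` (binary); ``covariates`` is an n x q numeric design
    without intercept (may be None).  With ``use_permutation=False`` the
    asymptotic Wald P-values are used instead of permutation (faster,
    reported the same way).  Genes whose fits fail are logged and skipped.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    t = np.asarray(tmb_any, dtype=float).ravel()
    n = len(y)
    if covariates is None:
        C = np.ones((n, 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        C = np.column_stack([np.ones(n), cov])

    rng = np.random.default_rng(seed)
    present = [g for g in pathway_genes if g in matrix.index]
    skipped = len(list(pathway_genes)) - len(present)
    if skipped:
        logger.info("screen: %d gene(s) absent from matrix, skipped", skipped)

    if use_permutation:
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
        # burden->expression permutations are shared across genes (the
        # exposure permuted is the mutation flag)
        Tp = _residualize(t[perm_idx], C)  # residualized permuted flags
        t_res = _residualize(t[None, :], C)[0]
        # covariate-only fit: warm start for the permuted logistic refits
        # (a permuted gene is null, so this model predicts them well)
        cov_fit = logistic_fit(y, C)
        warm = np.concatenate([[0.0], cov_fit.params])

    results: list[GeneScreenResult] = []
    for g in present:
        e = matrix.loc[g].to_numpy(dtype=float)
        try:
            beta, se_b = _ols_beta_se(e, t, C)
            fit = logistic_fit(y, np.column_stack([e, C]))
        except Exception as exc:
            logger.warning("gene %s: fit failed (%s); skipped", g, exc)
            continue
        b_out, se_out = fit.params[0], fit.bse[0]

        if use_permutation:
            # OLS: via Frisch-Waugh, the x-coefficient is
            # <x_res, e_res> / ||x_res||^2 for x residualized on C
            e_res = _residualize(e[None, :], C)[0]
            obs_t = abs((t_res @ e_res) / (t_res @ t_res))
            perm_t = np.abs((Tp @ e_res) / (Tp * Tp).sum(axis=1))
            p1 = float((1 + np.sum(perm_t >= obs_t)) / (n_perm + 1))

            Gp = e[perm_idx]
            z_obs = abs(b_out / se_out)
            z_perm = np.abs(batched_logistic_varying_column(y, C, Gp, beta0=warm))
            p2 = float((1 + np.sum(z_perm >= z_obs)) / (n_perm + 1))
        else:
            p1 = float(2 * norm.sf(abs(beta / se_b)))
            p2 = float(2 * norm.sf(abs(b_out / se_out)))

        results.append(
            GeneScreenResult(
                gene=g,
                beta_tmb_expr=beta,
                se_tmb_expr=se_b,
                p_tmb_expr=p1,
                or_expr_outcome=float(np.exp(b_out)),
                ci_low=float(np.exp(b_out - 1.959964 * se_out)),
                ci_high=float(np.exp(b_out + 1.959964 * se_out)),
                p_expr_outcome=p2,
                passes_screen=bool(p1 < alpha and p2 < alpha),
            )
        )
    return results


def screen_frame(results: list[GeneScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


class MediationModel:
    """Proportion of the burden-outcome effect mediated by one gene.

    ``fit()`` estimates total (logit of outcome on the mutation flag and
    covariates) and direct (adding the gene's expression) effects, and the
    proportion mediated ``(total - direct) / total`` with a percentile
    bootstrap CI.  When |total| < 1e-6 the proportion is undefined and
    reported as None.
    """

    def __init__(self, matrix: pd.DataFrame, gene: str, tmb_any, outcome, covariates):
        if gene not in matrix.index:
            raise KeyError(f"gene {gene!r} not in matrix")
        self.gene = gene
        self.e = matrix.loc[gene].to_numpy(dtype=float)
        self.t = np.asarray(tmb_any, dtype=float).ravel()
        self.y = np.asarray(outcome, dtype=float).ravel()
        n = len(self.y)
        if covariates is None:
            self.C = np.ones((n, 1))
        else:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            self.C = np.column_stack([np.ones(n), cov])

    def _effects(self, idx=None) -> tuple[float, float]:
        sl = slice(None) if idx is None else idx
        t, e, y, C = self.t[sl], self.e[sl], self.y[sl], self.C[sl]
        total = logistic_fit(y, np.column_stack([t, C])).params[0]
        direct = logistic_fit(y, np.column_stack([t, e, C])).params[0]
        return float(total), float(direct)

    def fit(self, n_boot: int = 500, seed: int = 0, tol: float = 1e-6) -> MediationResult:
        total, direct = self._effects()
        if abs(total) < tol:
            return MediationResult(self.gene, total, direct, None, None, None, 0)
        prop = (total - direct) / total

        rng = np.random.default_rng(seed)
        n = len(self.y)
        props = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                tb, db = self._effects(idx)
            except Exception:
                continue  # resample produced a degenerate fit
            if abs(tb) >= tol:
                props.append((tb - db) / tb)
        if props:
            lo, hi = np.percentile(props, [2.5, 97.5])
        else:
            lo = hi = np.nan
        return MediationResult(
            self.gene, total, direct, float(prop), float(lo), float(hi), n_boot
        )


def mediation(
    matrix: pd.DataFrame,
    gene: str,
    tmb_any,
    outcome,
    covariates,
    n_boot: int = 500,
    seed: int = 0,
) -> MediationResult:
    """Functional wrapper over :class:`MediationModel`."""
    return MediationModel(matrix, gene, tmb_any, outcome, covariates).fit(
        n_boot=n_boot, seed=seed
    )
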