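"""Pathway-level expression association: a global test.

Tests whether the expression profile of a gene set carries information
about a binary outcome beyond the clinical covariates.  With ``mu`` the
fitted probabilities of the covariate-only logistic model, residuals
``r = y - mu``, and ``X`` the column-standardized (samples x genes)
expression of the set's genes, the statistic is the quadratic form

    T = r' X X' r / m,        m = number of genes used,

i.e. the average squared covariance between the outcome residual and each
standardized gene.  T is large when many genes in the set co-vary with the
part of the outcome the covariates cannot explain.

Significance is assessed by permutation by default: outcome labels are
permuted, the covariate model refit per permutation (vectorized across
permutations), and ``P = (1 + #{T_perm >= T_obs}) / (n_perm + 1)``.  An
asymptotic alternative moment-matches T to a scaled chi-squared using the
exact Bernoulli residual moments at the fitted probabilities; it ignores
the variability from covariate estimation and is offered as a fast
approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .glm import batched_logistic_residuals, logistic_fit

logger = logging.getLogger(__name__)


@dataclass
class GlobalTestResult:
    pathway: str
    tissue: str
    statistic: float
    p_value: float
    n_permutations: int
    method: str
    n_genes_used: int
    n_genes_missing: int


class GlobalTest:
    """Global test of a gene set's expression against case/control status.

    Parameters
    ----------
    matrix
        genes x samples expression matrix (log2 CPM, batch-adjusted when
        cohorts are pooled); columns must align with ``outcome``.
    outcome
        binary per-sample vector (1 = case).
    covariates
        n x q numeric design of adjustment covariates WITHOUT intercept
        (one is added), or None for the unadjusted test.
    pathway_genes
        gene identifiers of the set; genes absent from the matrix are
        logged and skipped, constant genes are dropped (standardization is
        undefined for them).
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        outcome,
        covariates,
        pathway_genes,
        pathway: str = "pathway",
        tissue: str = "tumor",
    ):
        self.y = np.asarray(outcome, dtype=float).ravel()
        if self.y.min() == self.y.max():
            raise ValueError("degenerate outcome: all samples in one class")
        n = len(self.y)
        if matrix.shape[1] != n:
            raise ValueError("matrix columns must align with outcome length")
        genes = list(pathway_genes)
        present = [g for g in genes if g in matrix.index]
        self.n_missing = len(genes) - len(present)
        if self.n_missing:
            logger.info(
                "%s: %d/%d pathway genes absent from matrix, skipped",
                pathway, self.n_missing, len(genes),
            )
        if not present:
            raise ValueError(f"no genes of {pathway!r} present in the matrix")
        E = matrix.loc[present].to_numpy(dtype=float).T  # samples x m
        sd = E.std(axis=0)
        nonconst = sd > 0
        E = E[:, nonconst]
        if E.shape[1] == 0:
            raise ValueError("all pathway genes constant across samples")
        self.X = (E - E.mean(axis=0)) / E[:, :].std(axis=0)
        self.m = self.X.shape[1]
        if covariates is None:
            C = np.ones((n, 1))
        else:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            C = np.column_stack([np.ones(n), C])
        self.C = C
        self.pathway = pathway
        self.tissue = tissue

    def _statistic(self, r: np.ndarray) -> float:
        u = self.X.T @ r
        return float(u @ u) / self.m

    def fit(
        self,
        n_perm: int = 1000,
        seed: int | None = 0,
        method: str = "permutation",
    ) -> GlobalTestResult:
        """Compute the statistic and its P-value.

        ``method='permutation'`` (default) permutes outcome labels and
        refits the covariate-only logistic model for each permutation;
        ``method='asymptotic'`` uses the moment-matched scaled chi-squared.
        """
        fit0 = logistic_fit(self.y, self.C)
        from scipy.special import expit

        mu = expit(self.C @ fit0.params)
        r = self.y - mu
        t_obs = self._statistic(r)

        if method == "asymptotic":
            p = self._asymptotic_p(t_obs, mu)
            return GlobalTestResult(
                self.pathway, self.tissue, t_obs, p, 0, "asymptotic",
                self.m, self.n_missing,
            )
        if method != "permutation":
            raise ValueError("method must be 'permutation' or 'asymptotic'")

        rng = np.random.default_rng(seed)
        n = len(self.y)
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
        Yp = self.y[perm_idx]  # (B, n)
        R = batched_logistic_residuals(Yp, self.C, beta0=fit0.params)
        U = R @ self.X  # (B, m)
        t_perm = (U**2).sum(axis=1) / self.m
        p = (1.0 + np.sum(t_perm >= t_obs)) / (n_perm + 1.0)
        return GlobalTestResult(
            self.pathway, self.tissue, t_obs, float(p), n_perm, "permutation",
            self.m, self.n_missing,
        )

    def _asymptotic_p(self, t_obs: float, mu: np.ndarray) -> float:
        # Satterthwaite: match mean and variance of T = r'Ar (independent
        # Bernoulli residuals at fixed mu) to g * chi2_h.
        v = mu * (1 - mu)
        A = (self.X @ self.X.T) / self.m
        a_diag = np.diag(A)
        mean_t = float(a_diag @ v)
        e4 = v * ((1 - mu) ** 3 + mu**3)  # E[(y-mu)^4]
        var_diag = float(a_diag**2 @ (e4 - v**2))
        off = A**2 * np.outer(v, v)
        var_off = 2.0 * float(off.sum() - np.diag(off).sum())
        var_t = var_diag + var_off
        if var_t <= 0 or mean_t <= 0:
            return 1.0
        g = var_t / (2 * mean_t)
        h = 2 * mean_t**2 / var_t
        return float(chi2.sf(t_obs / g, h))


def pathway_expression_tests(
    matrix: pd.DataFrame,
    outcome,
    covariates,
    coll,
    tissue: str = "tumor",
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "permutation",
) -> pd.DataFrame:
    """Run the global test for every pathway in a collection.

    Returns a tidy frame (pathway, tissue, statistic, p_value, n_genes_used,
    n_genes_missing, method) — the per-tissue summary used for reporting.
    """
    rows = []
    for p in coll:
        gt = GlobalTest(
            matrix, outcome, covariates, sorted(p.genes),
            pathway=p.name, tissue=tissue,
        )
        res = gt.fit(n_perm=n_perm, seed=seed, method=method)
        rows.append(res.__dict__)
    return pd.DataFrame(rows)
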