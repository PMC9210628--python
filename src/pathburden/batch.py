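"""Empirical-Bayes batch-effect adjustment (ComBat-style) for pooled cohorts.

Per-gene batch location and scale effects are estimated on standardized
data, shrunk toward parametric priors (normal for locations, inverse-gamma
for scales, hyperparameters by method of moments), and removed.  Biological
covariates — case/control status in this pipeline — are kept in the design
during estimation so the contrast of interest is not absorbed into the
batch means.

Only applied when pooling cohorts; within-cohort analyses use the
unadjusted log2-CPM matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class ConfoundedBatchError(ValueError):
    """Batch is confounded with (inseparable from) the covariate design."""


def _eb_iterate(s_data, gamma_hat, delta_hat, g_bar, t2, a_prior, b_prior, conv=1e-4):
    """Iterative solution for the EB-shrunk batch location/scale (one batch)."""
    n = s_data.shape[1]
    g_old, d_old = gamma_hat.copy(), delta_hat.copy()
    for _ in range(500):
        g_new = (t2 * n * gamma_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((s_data - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old).clip(min=1e-12)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old).clip(min=1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(
    matrix: pd.DataFrame,
    batch_labels,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Remove per-gene batch location/scale effects from a genes x samples
    matrix (log scale), preserving covariate-associated signal.

    Parameters
    ----------
    matrix
        genes x samples log-scale expression (e.g. log2 CPM).
    batch_labels
        length-n_samples batch assignment.
    covariates
        optional n_samples x q numeric design of biological covariates to
        protect (an intercept is handled internally; do not include one).

    A single batch returns the input unchanged.  Raises
    :class:`ConfoundedBatchError` when a covariate is perfectly predicted by
    batch membership (e.g. batch identical to outcome), in which case the
    batch effect is not estimable.
    """
    batch = pd.Series(list(batch_labels)).astype(str)
    levels = sorted(batch.unique())
    if len(levels) < 2:
        return matrix.copy()
    counts = batch.value_counts()
    small = [b for b in levels if counts[b] < 2]
    if small:
        raise ValueError(f"batch(es) with fewer than 2 samples: {', '.join(small)}")

    dat = matrix.to_numpy(dtype=float)  # G x n
    n_array = dat.shape[1]
    batch_design = np.column_stack([(batch == b).to_numpy(float) for b in levels])
    n_batches = batch_design.sum(axis=0)

    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        design = np.column_stack([batch_design, cov])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ConfoundedBatchError(
                "covariate design is confounded with batch; batch effects "
                "are not estimable"
            )
    else:
        design = batch_design
    q = design.shape[1] - len(levels)

    # per-gene OLS of expression on [batch one-hots, covariates]
    B_hat = np.linalg.solve(design.T @ design, design.T @ dat.T)  # p x G
    grand_mean = (n_batches / n_array) @ B_hat[: len(levels), :]  # G
    resid = dat - (design @ B_hat).T
    var_pooled = (resid**2).mean(axis=1)  # G
    var_pooled = var_pooled.clip(min=1e-12)

    stand_mean = np.tile(grand_mean[:, None], (1, n_array))
    if q > 0:
        tmp = design.copy()
        tmp[:, : len(levels)] = 0
        stand_mean = stand_mean + (tmp @ B_hat).T
    s_data = (dat - stand_mean) / np.sqrt(var_pooled)[:, None]

    bayes = s_data.copy()
    for k, b in enumerate(levels):
        idx = (batch == b).to_numpy()
        sb = s_data[:, idx]
        gamma_hat = sb.mean(axis=1)
        delta_hat = sb.var(axis=1, ddof=1)
        g_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
        a_prior = (2 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        g_star, d_star = _eb_iterate(sb, gamma_hat, delta_hat, g_bar, t2, a_prior, b_prior)
        bayes[:, idx] = (sb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = bayes * np.sqrt(var_pooled)[:, None] + stand_mean
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
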