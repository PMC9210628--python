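"""Between-sample normalization of RNA-seq count libraries.

Implements trimmed mean of M-values (TMM): each sample receives a scaling
factor computed from the weighted mean of gene-wise log2 fold changes (M)
against a reference sample, after trimming the most extreme 30% of M values
and 5% of average-abundance (A) values on each side.  Weights are the
inverse asymptotic (delta-method) variances of the M values.  The reference
is the sample whose 75th percentile of count/library-size is closest to the
mean across samples.  Factors are rescaled to have geometric mean one, and
the effective library size used for CPM is library_size x factor.

log2 counts-per-million are computed as
``log2((count + prior) / (effective_library_size + 2 * prior) * 1e6)``
with a default prior count of 0.5, which keeps zeros finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class NormalizedMatrix:
    """TMM-normalized expression container.

    Attributes
    ----------
    log2_cpm
        genes x samples DataFrame of log2 CPM on effective library sizes.
    tmm_factors
        per-sample scaling factors, geometric mean 1.
    library_sizes
        per-sample raw total counts.
    counts
        the raw genes x samples count matrix the object was built from.
    """

    log2_cpm: pd.DataFrame
    tmm_factors: pd.Series
    library_sizes: pd.Series
    counts: pd.DataFrame

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.tmm_factors


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**f)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> pd.Series:
    """Per-sample TMM scaling factors (geometric mean 1)."""
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be nonnegative")
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0].tolist()
        raise ValueError(f"all-zero sample(s): {', '.join(map(str, bad))}")
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")

    if ref_sample is None:
        f75 = np.quantile(mat / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_sample)

    ref = mat[:, ref_idx]
    n_ref = lib[ref_idx]
    f = np.array(
        [
            _tmm_pair_factor(mat[:, j], ref, lib[j], n_ref, trim_m, trim_a)
            for j in range(mat.shape[1])
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="tmm_factor")


def log2_cpm(
    counts: pd.DataFrame,
    effective_lib_sizes: pd.Series | np.ndarray,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 CPM with a prior count, on effective library sizes."""
    lib = np.asarray(effective_lib_sizes, dtype=float)
    mat = counts.to_numpy(dtype=float)
    vals = np.log2((mat + prior_count) / (lib + 2 * prior_count) * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def tmm_normalize(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    prior_count: float = 0.5,
) -> NormalizedMatrix:
    """TMM-normalize a genes x samples raw count matrix."""
    factors = tmm_factors(counts, trim_m=trim_m, trim_a=trim_a)
    lib = counts.sum(axis=0).astype(float)
    eff = lib * factors
    return NormalizedMatrix(
        log2_cpm=log2_cpm(counts, eff, prior_count=prior_count),
        tmm_factors=factors,
        library_sizes=lib,
        counts=counts,
    )


def read_counts_tsv(path) -> pd.DataFrame:
    """Gene x sample integer count matrix with gene ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")
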