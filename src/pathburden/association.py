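"""Adjusted logistic association models and between-cohort heterogeneity.

The exposure is a pathway mutation burden — either the binary any-mutation
flag or the log2-transformed per-Mb rate, so that a one-unit effect on the
log2 scale reads as the odds ratio per doubling of burden.  Three covariate
schedules are supported:

* ``basic``    — cohort membership + molecular subtype
* ``main``     — cohort + age + menopausal status + subtype + stage
* ``advanced`` — main + treatment (surgery, chemo, radio, hormonal therapy)

Categorical covariates enter as indicator columns against explicit
reference levels (cohortA, Luminal A, stage I, premenopausal, no
treatment); "unknown" is kept as its own level rather than dropping rows.
Cohort-specific estimates are compared with Cochran's Q (fixed-effect,
inverse-variance weights).  Matched pairs are analyzed unconditionally with
the matching factor (subtype) as a covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .design import SUBTYPES
from .glm import LogisticFit, logistic_fit

Z975 = 1.959964  # used both for CIs and to recover SEs from printed CIs

SCHEDULES = {
    "basic": ["cohort", "subtype"],
    "main": ["cohort", "age", "menopause", "subtype", "stage"],
    "advanced": [
        "cohort", "age", "menopause", "subtype", "stage",
        "surgery", "chemo", "radio", "hormonal",
    ],
}

#: reference level per categorical covariate (first level = reference)
CATEGORICAL_LEVELS = {
    "menopause": ["pre", "post", "unknown"],
    "subtype": SUBTYPES,
    "stage": ["I", "II", "III"],
    "surgery": ["no", "yes", "unknown"],
    "chemo": ["no", "yes", "unknown"],
    "radio": ["no", "yes", "unknown"],
    "hormonal": ["no", "yes", "unknown"],
}


@dataclass
class AssocResult:
    """One adjusted odds-ratio estimate (Table-2-style row)."""

    exposure: str
    pathway: str
    cohort: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str
    n_cases: int
    n_controls: int
    log_or: float = field(repr=False, default=np.nan)
    se: float = field(repr=False, default=np.nan)


@dataclass
class HeterogeneityResult:
    q_stat: float
    df: int
    p_value: float


def cochran_q(estimates: list[tuple[float, float]]) -> HeterogeneityResult:
    """Cochran's Q homogeneity test over (log_or, se) pairs.

    Fixed-effect inverse-variance weights ``w_i = 1/se_i^2``; the statistic
    is the weighted sum of squared deviations from the pooled estimate,
    referred to chi-squared with k-1 degrees of freedom.
    """
    if len(estimates) < 2:
        raise ValueError("need at least 2 estimates")
    theta = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    pooled = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(estimates) - 1
    return HeterogeneityResult(q, df, float(chi2.sf(q, df)))


def cochran_q_from_or_ci(rows: list[tuple[float, float, float]]) -> HeterogeneityResult:
    """Cochran's Q from (odds_ratio, ci_low, ci_high) triples.

    The SE is recovered from 95% Wald bounds as
    ``(ln(ci_high) - ln(ci_low)) / (2 * 1.959964)``.
    """
    est = []
    for or_, lo, hi in rows:
        if min(or_, lo, hi) <= 0:
            raise ValueError("odds ratios and CI bounds must be positive")
        est.append((np.log(or_), (np.log(hi) - np.log(lo)) / (2 * Z975)))
    return cochran_q(est)


def build_design(
    data: pd.DataFrame,
    schedule: str,
    exposure_col: str,
    drop_constant: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Outcome vector and design matrix (intercept, exposure, covariates).

    Categorical covariates are expanded against the reference levels above;
    indicator columns with no variation in the data at hand (e.g. the cohort
    indicator inside a single-cohort fit, or an absent "unknown" level) are
    dropped so the design stays full rank.
    """
    if schedule not in SCHEDULES:
        raise ValueError(f"unknown schedule {schedule!r}; one of {sorted(SCHEDULES)}")
    y = data["status"].to_numpy(dtype=float)
    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["intercept"]
    cols.append(data[exposure_col].to_numpy(dtype=float))
    names.append(exposure_col)
    for cov in SCHEDULES[schedule]:
        if cov == "age":
            cols.append(data["age"].to_numpy(dtype=float))
            names.append("age")
        elif cov == "cohort":
            levels = sorted(data["cohort"].astype(str).unique())
            for lev in levels[1:]:
                cols.append((data["cohort"].astype(str) == lev).to_numpy(float))
                names.append(f"cohort[{lev}]")
        else:
            levels = CATEGORICAL_LEVELS[cov]
            vals = data[cov].astype(str)
            unexpected = set(vals.unique()) - set(levels)
            if unexpected:
                raise ValueError(f"{cov}: unexpected level(s) {sorted(unexpected)}")
            for lev in levels[1:]:
                cols.append((vals == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    if drop_constant:
        keep = [0] + [
            j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0
        ]
        X = X[:, keep]
        names = [names[j] for j in keep]
    return y, X, names


def _exposure_column(exposure: str, pathway: str) -> str:
    return f"{exposure}:{pathway}"


def attach_exposures(clinical: pd.DataFrame, tmb_table: pd.DataFrame) -> pd.DataFrame:
    """Merge per-pathway burden columns onto the clinical/analysis table."""
    out = clinical.copy()
    for value in ("any_mutation", "log2_tmb"):
        wide = tmb_table.pivot(index="sample_id", columns="pathway", values=value)
        for pw in wide.columns:
            out[_exposure_column(value, pw)] = (
                out["id"].map(wide[pw]).astype(float)
            )
    return out


class PathwayAssociationModel:
    """Logistic model of case/control status on a pathway burden exposure.

    Statsmodels-style: construct from data, then :meth:`fit` returns a
    :class:`PathwayAssociationResults` holding the pooled and per-cohort
    odds ratios, Wald CIs and P-values, and the between-cohort Cochran's Q.

    Parameters
    ----------
    data
        Per-sample analysis table with ``status`` (1 case / 0 control),
        ``cohort``, the schedule covariates, and burden exposure columns as
        produced by :func:`attach_exposures`.
    pathway, exposure
        Which burden column to use; ``exposure`` is ``any_mutation`` or
        ``log2_tmb`` (the latter estimates an OR per doubling of TMB).
    schedule
        Covariate schedule: basic, main, or advanced.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        pathway: str,
        exposure: str = "any_mutation",
        schedule: str = "main",
    ):
        if exposure not in ("any_mutation", "log2_tmb"):
            raise ValueError("exposure must be 'any_mutation' or 'log2_tmb'")
        self.data = data
        self.pathway = pathway
        self.exposure = exposure
        self.schedule = schedule
        self.exposure_col = _exposure_column(exposure, pathway)
        if self.exposure_col not in data.columns:
            raise KeyError(f"missing exposure column {self.exposure_col!r}")

    @classmethod
    def from_frames(
        cls,
        clinical: pd.DataFrame,
        tmb_table: pd.DataFrame,
        pathway: str,
        exposure: str = "any_mutation",
        schedule: str = "main",
    ) -> "PathwayAssociationModel":
        return cls(attach_exposures(clinical, tmb_table), pathway, exposure, schedule)

    def _fit_one(self, sub: pd.DataFrame, cohort_tag: str) -> AssocResult:
        y, X, names = build_design(sub, self.schedule, self.exposure_col)
        try:
            fit = logistic_fit(y, X, colnames=names)
        except Exception as exc:
            raise type(exc)(
                f"[pathway={self.pathway} model={self.schedule} "
                f"cohort={cohort_tag}] {exc}"
            ) from exc
        j = names.index(self.exposure_col)
        b, se = fit.params[j], fit.bse[j]
        return AssocResult(
            exposure=self.exposure,
            pathway=self.pathway,
            cohort=cohort_tag,
            odds_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - Z975 * se)),
            ci_high=float(np.exp(b + Z975 * se)),
            p_value=float(2 * norm.sf(abs(b / se))),
            model=self.schedule,
            n_cases=int(sub["status"].sum()),
            n_controls=int((1 - sub["status"]).sum()),
            log_or=float(b),
            se=float(se),
        )

    def fit(self, per_cohort: bool = True) -> "PathwayAssociationResults":
        results = {"pooled": self._fit_one(self.data, "pooled")}
        het = None
        if per_cohort:
            cohorts = sorted(self.data["cohort"].astype(str).unique())
            if len(cohorts) > 1:
                for c in cohorts:
                    results[c] = self._fit_one(
                        self.data[self.data["cohort"].astype(str) == c], c
                    )
                het = cochran_q(
                    [(results[c].log_or, results[c].se) for c in cohorts]
                )
        return PathwayAssociationResults(self, results, het)


@dataclass
class PathwayAssociationResults:
    """Fitted pooled and per-cohort associations plus heterogeneity test."""

    model: PathwayAssociationModel
    by_cohort: dict[str, AssocResult]
    heterogeneity: HeterogeneityResult | None

    @property
    def pooled(self) -> AssocResult:
        return self.by_cohort["pooled"]

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "pathway": r.pathway,
                "exposure": r.exposure,
                "model": r.model,
                "cohort": r.cohort,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
            }
            for r in self.by_cohort.values()
        ]
        df = pd.DataFrame(rows)
        if self.heterogeneity is not None:
            df["p_heterogeneity"] = np.where(
                df["cohort"] == "pooled", self.heterogeneity.p_value, np.nan
            )
        return df

    def summary(self) -> str:
        lines = [
            f"Pathway burden association — pathway={self.model.pathway}, "
            f"exposure={self.model.exposure}, model={self.model.schedule}",
            f"{'cohort':<10}{'cases':>6}{'controls':>9}{'OR':>8}"
            f"{'95% CI':>18}{'P':>10}",
        ]
        for tag, r in self.by_cohort.items():
            lines.append(
                f"{tag:<10}{r.n_cases:>6}{r.n_controls:>9}{r.odds_ratio:>8.2f}"
                f"{'(%.2f, %.2f)' % (r.ci_low, r.ci_high):>18}{r.p_value:>10.3g}"
            )
        if self.heterogeneity is not None:
            h = self.heterogeneity
            lines.append(
                f"Between-cohort heterogeneity: Q={h.q_stat:.3f} "
                f"df={h.df} P={h.p_value:.2f}"
            )
        return "\n".join(lines)

    def plot_forest(self, ax=None):
        """Forest plot of the per-cohort and pooled odds ratios."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 0.6 * len(self.by_cohort) + 1))
        tags = list(self.by_cohort)
        for i, tag in enumerate(tags):
            r = self.by_cohort[tag]
            ax.errorbar(
                r.odds_ratio,
                i,
                xerr=[[r.odds_ratio - r.ci_low], [r.ci_high - r.odds_ratio]],
                fmt="s" if tag == "pooled" else "o",
                color="k",
                capsize=3,
            )
        ax.axvline(1.0, ls="--", color="grey", lw=0.8)
        ax.set_yticks(range(len(tags)), tags)
        ax.set_xscale("log")
        ax.set_xlabel("odds ratio (95% CI)")
        ax.set_title(f"{self.model.pathway} ({self.model.exposure})")
        return ax


def run_model_schedule(
    data: pd.DataFrame,
    pathway: str,
    exposure: str,
    schedule: str,
) -> AssocResult:
    """Single pooled adjusted OR for one pathway/exposure/schedule."""
    return PathwayAssociationModel(data, pathway, exposure, schedule).fit(
        per_cohort=False
    ).pooled


def stratify_er(
    data: pd.DataFrame,
    pathway: str,
    exposure: str = "any_mutation",
    schedule: str = "main",
    min_per_class: int = 10,
) -> dict[str, "PathwayAssociationResults | str"]:
    """Fit the association separately within ER-positive and ER-negative
    strata; strata too small (or degenerate) are reported as skipped."""
    out: dict[str, PathwayAssociationResults | str] = {}
    for stratum in ("pos", "neg"):
        sub = data[data["er"].astype(str) == stratum]
        n_case = int(sub["status"].sum()) if len(sub) else 0
        n_ctrl = len(sub) - n_case
        if min(n_case, n_ctrl) < min_per_class:
            out[stratum] = (
                f"skipped: stratum ER={stratum} too small "
                f"({n_case} cases / {n_ctrl} controls)"
            )
            continue
        try:
            out[stratum] = PathwayAssociationModel(
                sub, pathway, exposure, schedule
            ).fit()
        except Exception as exc:  # degenerate stratum: report, don't raise
            out[stratum] = f"skipped: {exc}"
    return out


def sensitivity_exclusions(
    data: pd.DataFrame,
    mode: str,
) -> pd.DataFrame:
    """Drop whole matched pairs containing a flagged member.

    Modes: ``drop_nonbc_death_pairs`` removes pairs whose case died of a
    non-breast-cancer cause (flag column ``nonbc_death``);
    ``drop_neoadjuvant_pairs`` removes pairs with any member treated with
    neoadjuvant chemotherapy (flag column ``neoadjuvant``).
    """
    flags = {
        "drop_nonbc_death_pairs": "nonbc_death",
        "drop_neoadjuvant_pairs": "neoadjuvant",
    }
    if mode not in flags:
        raise ValueError(f"unknown mode {mode!r}")
    col = flags[mode]
    if "pair_id" not in data.columns:
        raise ValueError("data must carry pair_id (matched pairs)")
    flagged_pairs = set(data.loc[data[col].astype(bool), "pair_id"])
    return data[~data["pair_id"].isin(flagged_pairs)].copy()
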