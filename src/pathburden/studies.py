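"""Simulation studies: operating characteristics of the pipeline.

Each study runs the full analysis chain (generate -> classify/match ->
normalize -> test) against synthetic cohorts with known truth, and returns
the measured operating characteristic: type-I error calibration of the
global test, tumor-vs-normal discrimination power, coverage of the
adjusted odds-ratio estimator, and mediation-proportion recovery.  These
are the package's own quality-control experiments; the same entry points
back both the test suite and the reproduction script.

Study sizes are arguments with defaults chosen to finish on a single CPU
in minutes; all randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import association as am
from .batch import combat_adjust
from .design import build_matched_dataset
from .glm import logistic_fit
from .globaltest import GlobalTest
from .mediation import MediationModel, MediationResult
from .normalize import tmm_normalize
from .registry import PathwayCollection
from .simulate import (
    CohortSpec,
    EffectSpec,
    demo_pathway_collection,
    generate_study,
)

TEST_PATHWAY = "glucocorticoid"


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _main_covariates(data: pd.DataFrame) -> np.ndarray:
    """Main-schedule covariate design without intercept or exposure."""
    _, X, names = am.build_design(data.assign(_null=0.0), "main", "_null")
    keep = [j for j, nm in enumerate(names) if nm not in ("intercept", "_null")]
    return X[:, keep]


def _expression_pvalues(
    coll: PathwayCollection,
    eff: EffectSpec,
    n_per_cohort: int,
    n_perm: int,
    seed: int,
    tissues: tuple[str, ...] = ("tumor",),
) -> dict[str, float]:
    """One replicate: generate, match, normalize, pool-adjust, global test.

    Returns tissue -> P-value for the test pathway.
    """
    genes = sorted(coll[TEST_PATHWAY].genes)
    study = generate_study(
        coll,
        [CohortSpec(n_per_cohort, "cohortA"), CohortSpec(n_per_cohort, "cohortB")],
        eff,
        seed=seed,
        tissues=tissues,
        expression_genes=genes,
    )
    matched, _, _ = build_matched_dataset(study.patients, seed=seed + 1)
    y = matched["status"].to_numpy(dtype=float)
    cov = _main_covariates(matched)
    out: dict[str, float] = {}
    for tissue in tissues:
        counts = study.expression[tissue][matched["id"]]
        mat = tmm_normalize(counts).log2_cpm
        # outcome-free adjustment: matching balances case status across the
        # cohorts, and keeping the outcome out of the batch model preserves
        # the exactness of the downstream permutation test
        mat = combat_adjust(mat, matched["cohort"])
        res = GlobalTest(mat, y, cov, genes, pathway=TEST_PATHWAY, tissue=tissue).fit(
            n_perm=n_perm, seed=seed + 2
        )
        out[tissue] = res.p_value
    return out


@dataclass
class CalibrationResult:
    rejection_rate: float
    p_values: np.ndarray
    alpha: float
    n_replicates: int


def global_test_null_calibration(
    n_per_cohort: int = 200,
    n_replicates: int = 1000,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    coll: PathwayCollection | None = None,
) -> CalibrationResult:
    """Type-I error of the pathway expression test under the causal null.

    Two cohorts are generated with every effect zero, matched, TMM
    normalized, batch-adjusted, and the permutation global test run on the
    test pathway; the fraction of replicates with P < alpha estimates the
    empirical size, which should sit at the nominal level, and the P-value
    sample should be uniform.
    """
    coll = coll or demo_pathway_collection(0)
    seeds = _child_seeds(seed, n_replicates)
    ps = np.array(
        [
            _expression_pvalues(coll, EffectSpec.null(), n_per_cohort, n_perm, s)[
                "tumor"
            ]
            for s in seeds
        ]
    )
    return CalibrationResult(float((ps < alpha).mean()), ps, alpha, n_replicates)


@dataclass
class TissuePowerResult:
    tumor_rejection_rate: float
    normal_rejection_rate: float
    tumor_p: np.ndarray
    normal_p: np.ndarray


def tumor_normal_power(
    n_per_cohort: int = 200,
    n_replicates: int = 200,
    n_perm: int = 500,
    effect: float = 0.4,
    frac_genes: float = 0.2,
    alpha: float = 0.05,
    seed: int = 0,
    coll: PathwayCollection | None = None,
) -> TissuePowerResult:
    """Tumor-vs-normal discrimination of the expression test.

    An expression -> outcome effect is placed on a fraction of the test
    pathway's genes in tumor tissue (the generator couples the outcome to
    tumor expression only), so the tumor-tissue test should reject while
    the paired normal-tissue test stays at its nominal level.
    """
    coll = coll or demo_pathway_collection(0)
    genes = sorted(coll[TEST_PATHWAY].genes)
    rng = np.random.default_rng(seed)
    k = max(1, int(round(frac_genes * len(genes))))
    hit = list(rng.choice(genes, size=k, replace=False))
    eff = EffectSpec(
        expr_outcome_effect={g: effect for g in hit},
        batch_shift={},
        covariate_effects={},
    )
    seeds = _child_seeds(seed + 1, n_replicates)
    tp, np_ = [], []
    for s in seeds:
        pv = _expression_pvalues(
            coll, eff, n_per_cohort, n_perm, s, tissues=("tumor", "normal")
        )
        tp.append(pv["tumor"])
        np_.append(pv["normal"])
    tp, np_ = np.array(tp), np.array(np_)
    return TissuePowerResult(
        float((tp < alpha).mean()), float((np_ < alpha).mean()), tp, np_
    )


@dataclass
class RecoveryResult:
    coverage: float
    estimates: np.ndarray
    true_log_or: float
    n_replicates: int

    @property
    def mean_or(self) -> float:
        return float(np.exp(np.mean(self.estimates)))


def or_recovery(
    true_or: float = 1.5,
    n_patients: int = 2000,
    n_replicates: int = 200,
    seed: int = 0,
    coll: PathwayCollection | None = None,
) -> RecoveryResult:
    """Coverage of the main-model Wald CI for the OR per doubling of TMB.

    Cohorts are generated with a known odds ratio per doubling of the test
    pathway's burden; each replicate fits the main adjusted model on the
    eligible cases and controls and checks whether the 95% CI covers the
    truth.  Coverage should sit at its nominal 95%.
    """
    coll = coll or demo_pathway_collection(0)
    true_b = float(np.log(true_or))
    eff = EffectSpec(or_per_doubling_tmb={TEST_PATHWAY: true_or})
    seeds = _child_seeds(seed, n_replicates)
    est, covered = [], []
    half = n_patients // 2
    for s in seeds:
        study = generate_study(
            coll,
            [CohortSpec(half, "cohortA"), CohortSpec(n_patients - half, "cohortB")],
            eff,
            seed=s,
            tissues=(),
        )
        matched, _, _ = build_matched_dataset(study.patients, seed=s + 1)
        data = am.attach_exposures(matched, study.tmb)
        res = am.PathwayAssociationModel(
            data, TEST_PATHWAY, "log2_tmb", "main"
        ).fit(per_cohort=False).pooled
        est.append(res.log_or)
        covered.append(
            res.log_or - am.Z975 * res.se <= true_b <= res.log_or + am.Z975 * res.se
        )
    return RecoveryResult(
        float(np.mean(covered)), np.array(est), true_b, n_replicates
    )


def mediation_recovery(
    kind: str,
    n_patients: int = 5000,
    n_boot: int = 200,
    seed: int = 0,
    coll: PathwayCollection | None = None,
) -> MediationResult:
    """Recover the mediated proportion under three known constructions.

    ``full``: the burden-outcome effect flows entirely through one gene's
    expression, so the proportion mediated approaches 1.  ``null``: the
    burden affects the outcome directly and the probed gene is inert, so
    the proportion approaches 0.  ``inconsistent``: the gene's indirect
    path opposes the direct effect, so the proportion is negative.

    A single cohort is generated (no batch structure) and the mediation
    model is fit on the full cohort's 5-year event indicator.
    """
    coll = coll or demo_pathway_collection(0)
    gene = sorted(coll[TEST_PATHWAY].genes - set(coll.shared_genes))[0]
    base = dict(batch_shift={}, covariate_effects={})
    if kind == "full":
        eff = EffectSpec(
            tmb_expr_effect={gene: 2.0},
            expr_outcome_effect={gene: 1.0},
            **base,
        )
    elif kind == "null":
        eff = EffectSpec(or_per_doubling_tmb={TEST_PATHWAY: 1.8}, **base)
    elif kind == "inconsistent":
        eff = EffectSpec(
            or_per_doubling_tmb={TEST_PATHWAY: 2.5},
            tmb_expr_effect={gene: 2.0},
            expr_outcome_effect={gene: -0.3},
            **base,
        )
    else:
        raise ValueError("kind must be full, null, or inconsistent")

    genes = sorted(coll[TEST_PATHWAY].genes)
    study = generate_study(
        coll,
        [CohortSpec(n_patients, "cohortA")],
        eff,
        seed=seed,
        tissues=("tumor",),
        expression_genes=genes,
    )
    pts = study.patients
    y = pts["idfs_event"].to_numpy(dtype=float)
    counts = study.expression["tumor"][pts["id"]]
    mat = tmm_normalize(counts).log2_cpm
    tmb_any = (
        study.tmb[study.tmb["pathway"] == TEST_PATHWAY]
        .set_index("sample_id")["any_mutation"]
        .reindex(pts["id"])
        .to_numpy(dtype=float)
    )
    return MediationModel(mat, gene, tmb_any, y, None).fit(
        n_boot=n_boot, seed=seed + 1
    )


def crude_or_2x2(a: int, b: int, c: int, d: int) -> float:
    """Crude OR for exposed-case/unexposed-case/exposed-control/unexposed-
    control counts, computed through the logistic likelihood (equals the
    cross-product ratio ad/bc at the MLE)."""
    y = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    x = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    fit = logistic_fit(y, np.column_stack([np.ones_like(x), x]))
    return float(np.exp(fit.params[1]))
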