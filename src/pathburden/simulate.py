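"""Synthetic two-cohort study generator.

Emulates the data a matched extreme case-control prognosis study consumes:
per-patient clinical covariates with marginals resembling a breast-cancer
case-control table (age, menopause, receptor status, St Gallen subtype,
stage, treatment), per-gene somatic mutations, negative-binomial RNA-seq
counts for tumor and paired normal tissue, and a 5-year iDFS outcome.

The causal structure is configurable and mirrors the hypothesis under
study: pathway mutation burden raises the event odds directly (odds ratio
per doubling of TMB), shifts the expression of selected genes in *tumor*
tissue only, and gene expression can in turn carry its own effect on the
outcome — so mediation, tumor-vs-normal contrasts, and null calibration are
all constructible.  Setting every effect to zero gives the causal null.

Models:

* mutations — per-pathway count ~ Poisson(rate_per_Mb x coding_Mb), genes
  hit with probability proportional to coding length;
* expression — NB counts with per-sample log-normal depth, per-cohort
  additive log2 batch shift, and (tumor only) a log2 shift in mutated
  samples for genes with a configured effect;
* outcome — Bernoulli 5-year event from a logistic model (the design
  dichotomizes follow-up at five years, so no hazard model is needed);
  event times are uniform on (0, 5); non-events keep their drawn follow-up,
  which may fall short of five years (those patients are design-ineligible).

Everything is deterministic given the seeds; per-gene expression baselines
are derived from a hash of the gene symbol so tumor and normal matrices
share them across calls.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import classify_subtype
from .registry import PathwayCollection, PathwaySet
from .tmb import compute_tmb

VARIANT_CLASS_PROBS = {
    "Missense_Mutation": 0.70,
    "Nonsense_Mutation": 0.10,
    "Frame_Shift_Del": 0.06,
    "Frame_Shift_Ins": 0.04,
    "Splice_Site": 0.05,
    "In_Frame_Del": 0.03,
    "In_Frame_Ins": 0.02,
}


@dataclass
class CohortSpec:
    """Marginal covariate distributions for one synthetic cohort."""

    n_patients: int
    cohort_label: str
    age_mean_sd: tuple[float, float] = (54.0, 13.0)
    subtype_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "LuminalA": 0.21,
            "LuminalB": 0.40,
            "TNBC": 0.19,
            "HER2": 0.12,
            "Unclassified": 0.08,
        }
    )
    stage_probs: Mapping[str, float] = field(
        default_factory=lambda: {"I": 0.15, "II": 0.55, "III": 0.30}
    )
    er_positive_prob: float = 0.64
    followup_years_range: tuple[float, float] = (1.0, 10.0)
    seed: int = 0
    unknown_menopause_rate: float = 0.06
    unknown_treatment_rate: float = 0.10
    ki67_cutoff: float = 20.0

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        for name, probs in (
            ("subtype_probs", self.subtype_probs),
            ("stage_probs", self.stage_probs),
        ):
            s = float(sum(probs.values()))
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {s})")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} has negative entries")
        if not 0 <= self.er_positive_prob <= 1:
            raise ValueError("er_positive_prob must be in [0, 1]")
        lo, hi = self.followup_years_range
        if lo < 0 or hi <= lo:
            raise ValueError("followup_years_range must be a positive interval")


@dataclass
class EffectSpec:
    """Causal effect configuration for the generator.

    ``or_per_doubling_tmb`` maps pathway -> odds ratio per doubling of its
    TMB; ``tmb_expr_effect`` maps gene -> log2-CPM shift in tumor tissue
    when the gene's pathway carries any mutation; ``expr_outcome_effect``
    maps gene -> log-odds per unit of (centered) log2 CPM.  ``batch_shift``
    is a per-cohort additive log2-scale expression offset applied to both
    tissues (a cohort/platform effect).  All zero / empty = causal null.
    """

    baseline_event_logit: float = -1.0
    or_per_doubling_tmb: Mapping[str, float] = field(default_factory=dict)
    mutation_rate_per_mb: Mapping[str, float] = field(default_factory=dict)
    default_mutation_rate: float = 0.5
    expr_outcome_effect: Mapping[str, float] = field(default_factory=dict)
    tmb_expr_effect: Mapping[str, float] = field(default_factory=dict)
    batch_shift: Mapping[str, float] = field(
        default_factory=lambda: {"cohortB": 0.5}
    )
    dispersion: float = 0.3
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "age_per_decade": 0.3,
            "postmenopausal": 0.2,
            "stageII": 0.5,
            "stageIII": 1.0,
        }
    )

    def validate(self) -> None:
        if any(v <= 0 for v in self.or_per_doubling_tmb.values()):
            raise ValueError("odds ratios must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.default_mutation_rate < 0 or any(
            v < 0 for v in self.mutation_rate_per_mb.values()
        ):
            raise ValueError("mutation rates must be nonnegative")

    @classmethod
    def null(cls) -> "EffectSpec":
        """All effects zero: the generator's causal null."""
        return cls(
            baseline_event_logit=-1.0,
            default_mutation_rate=0.5,
            batch_shift={},
            covariate_effects={},
        )


def generate_patients(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort's clinical table (outcome fields left event-free).

    Receptor status, Ki-67 and the subtype label are generated jointly so
    that the St Gallen rule applied to the receptors reproduces the drawn
    subtype exactly (Unclassified patients get an unknown HER2).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    mean, sd = spec.age_mean_sd
    age = np.clip(rng.normal(mean, sd, n), 23, 90).round(1)

    p_post = expit((age - 50.0) / 3.0)
    meno = np.where(rng.random(n) < p_post, "post", "pre")
    meno = np.where(rng.random(n) < spec.unknown_menopause_rate, "unknown", meno)

    subtype_levels = list(spec.subtype_probs)
    subtype = rng.choice(
        subtype_levels, size=n, p=[spec.subtype_probs[s] for s in subtype_levels]
    )
    er = np.empty(n, dtype=object)
    pr = np.empty(n, dtype=object)
    her2 = np.empty(n, dtype=object)
    ki67 = np.empty(n)
    cut = spec.ki67_cutoff
    for i, st in enumerate(subtype):
        if st == "LuminalA":
            er[i], pr[i], her2[i] = "pos", "pos", "neg"
            ki67[i] = rng.uniform(5, cut - 0.5)
        elif st == "LuminalB":
            er[i] = "pos"
            variant = rng.integers(3)
            if variant == 0:  # HER2-positive luminal
                pr[i], her2[i] = "pos", "pos"
                ki67[i] = rng.uniform(5, 60)
            elif variant == 1:  # high Ki-67
                pr[i], her2[i] = "pos", "neg"
                ki67[i] = rng.uniform(cut, 60)
            else:  # PR-negative
                pr[i], her2[i] = "neg", "neg"
                ki67[i] = rng.uniform(5, 60)
        elif st == "TNBC":
            er[i], pr[i], her2[i] = "neg", "neg", "neg"
            ki67[i] = rng.uniform(5, 80)
        elif st == "HER2":
            er[i], pr[i], her2[i] = "neg", "neg", "pos"
            ki67[i] = rng.uniform(5, 80)
        else:  # Unclassified: HER2 not determined
            her2[i] = "unknown"
            if rng.random() < spec.er_positive_prob:
                er[i], pr[i] = "pos", "pos"
                ki67[i] = rng.uniform(5, cut - 0.5)
            else:
                er[i], pr[i] = "neg", "pos"
                ki67[i] = rng.uniform(5, 60)

    stage_levels = list(spec.stage_probs)
    stage = rng.choice(
        stage_levels, size=n, p=[spec.stage_probs[s] for s in stage_levels]
    )

    def _treat(p_yes: float, cond=None) -> np.ndarray:
        yes = rng.random(n) < (p_yes if cond is None else np.where(cond, p_yes, 0.15))
        out = np.where(yes, "yes", "no").astype(object)
        out[rng.random(n) < spec.unknown_treatment_rate] = "unknown"
        return out

    surgery = _treat(0.95)
    chemo = _treat(0.85)
    radio = _treat(0.50)
    hormonal = _treat(0.85, cond=(er == "pos"))
    neoadjuvant = rng.random(n) < 0.05

    lo, hi = spec.followup_years_range
    followup = rng.uniform(lo, hi, n).round(3)

    df = pd.DataFrame(
        {
            "id": [f"{spec.cohort_label}-{i:05d}" for i in range(n)],
            "cohort": spec.cohort_label,
            "age": age,
            "menopause": meno,
            "er": er,
            "pr": pr,
            "her2": her2,
            "ki67": ki67.round(1),
            "subtype": subtype,
            "stage": stage,
            "surgery": surgery,
            "chemo": chemo,
            "radio": radio,
            "hormonal": hormonal,
            "neoadjuvant": neoadjuvant,
            "nonbc_death": False,
            "followup_years": followup,
            "idfs_event": False,
            "idfs_time_years": followup,
        }
    )
    # internal consistency with the classifier
    check = [
        classify_subtype(r.er, r.pr, r.her2, r.ki67, cut) for r in df.itertuples()
    ]
    assert list(df["subtype"]) == check, "generator/classifier subtype mismatch"
    return df


def generate_mutations(
    patients: pd.DataFrame,
    coll: PathwayCollection,
    eff: EffectSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson somatic mutation calls per pathway.

    Each patient's count in pathway P is Poisson with mean
    ``rate_per_Mb(P) x coding_Mb(P)``; mutated genes are drawn with
    probability proportional to coding length, variant classes from a fixed
    nonsynonymous mix.  Returns a MAF-like frame.
    """
    eff.validate()
    rng = np.random.default_rng(seed)
    classes = list(VARIANT_CLASS_PROBS)
    class_p = np.array([VARIANT_CLASS_PROBS[c] for c in classes])
    class_p = class_p / class_p.sum()
    rows: list[tuple[str, str, str]] = []
    ids = patients["id"].tolist()
    for p in coll:
        rate = eff.mutation_rate_per_mb.get(p.name, eff.default_mutation_rate)
        lam = rate * p.total_coding_length_mb
        genes = sorted(p.genes)
        gl = np.array([p.coding_length_bp[g] for g in genes], dtype=float)
        gp = gl / gl.sum()
        counts = rng.poisson(lam, len(ids))
        for pid, k in zip(ids, counts):
            if k == 0:
                continue
            hit = rng.choice(len(genes), size=k, p=gp)
            vc = rng.choice(classes, size=k, p=class_p)
            rows.extend((pid, genes[j], c) for j, c in zip(hit, vc))
    return pd.DataFrame(
        rows, columns=["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]
    )


def _gene_baseline(gene: str) -> float:
    """Stable per-gene baseline log2 expression (same across calls)."""
    h = zlib.crc32(gene.encode()) & 0x7FFFFFFF
    g = np.random.default_rng(h)
    return float(g.normal(5.0, 2.0))


def generate_expression(
    patients: pd.DataFrame,
    mutations: pd.DataFrame,
    genes: Sequence[str],
    eff: EffectSpec,
    tissue: str = "tumor",
    seed: int = 0,
    coll: PathwayCollection | None = None,
    mean_library_size: float = 2e6,
) -> pd.DataFrame:
    """Negative-binomial genes x samples count matrix for one tissue.

    Tumor tissue: genes with a configured ``tmb_expr_effect`` are shifted by
    that many log2 units in samples whose pathway carries any mutation
    (pathway membership from ``coll`` when given, else "any mutation in the
    ``genes`` panel").  Normal tissue never receives mutation effects.
    Both tissues receive the per-cohort batch shift.
    """
    if tissue not in ("tumor", "normal"):
        raise ValueError("tissue must be 'tumor' or 'normal'")
    if len(genes) == 0:
        raise ValueError("gene list is empty")
    eff.validate()
    rng = np.random.default_rng(seed)
    ids = patients["id"].tolist()
    n = len(ids)

    # per-sample pathway-mutated indicator for each effect gene
    mut_flags: dict[str, np.ndarray] = {}
    if eff.tmb_expr_effect and tissue == "tumor":
        by_sample = mutations.groupby("Tumor_Sample_Barcode")["Hugo_Symbol"].agg(set)
        for g in eff.tmb_expr_effect:
            if coll is not None:
                members = set()
                for p in coll:
                    if g in p.genes:
                        members = p.genes
                        break
                members = members or {g}
            else:
                members = set(genes)
            flag = np.array(
                [bool(by_sample.get(pid, set()) & members) for pid in ids], float
            )
            mut_flags[g] = flag

    shift = np.array(
        [eff.batch_shift.get(c, 0.0) for c in patients["cohort"]], dtype=float
    )
    depth = rng.lognormal(0.0, 0.3, n)

    base = np.array([_gene_baseline(g) for g in genes])
    log2_mu = base[:, None] + shift[None, :]
    if tissue == "tumor":
        for g, delta in eff.tmb_expr_effect.items():
            if g in genes:
                gi = list(genes).index(g)
                log2_mu[gi] += delta * mut_flags[g]
    mu = (2.0**log2_mu) * depth[None, :]
    # scale so an average sample has roughly mean_library_size total counts
    mu *= mean_library_size / (2.0**base).sum()

    if eff.dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / eff.dispersion
        counts = rng.poisson(rng.gamma(shape, mu / shape))
    return pd.DataFrame(counts.astype(np.int64), index=list(genes), columns=ids)


def generate_outcome(
    patients: pd.DataFrame,
    tmb_table: pd.DataFrame,
    expr: pd.DataFrame | None,
    eff: EffectSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill iDFS outcome fields from the configured logistic model.

    The 5-year event probability is ``expit(logit)`` with

        logit = baseline + sum_p ln(OR_p) * log2TMB_p
                + sum_g beta_g * centered_log2CPM_g + covariate effects.

    Events get a time uniform on (0, 5) with follow-up ending at the event;
    non-events keep the follow-up drawn at patient generation.  A fraction
    of events are flagged as non-breast-cancer deaths for the sensitivity
    exclusion path.
    """
    eff.validate()
    rng = np.random.default_rng(seed)
    out = patients.copy().reset_index(drop=True)
    n = len(out)
    logit = np.full(n, eff.baseline_event_logit, dtype=float)

    if eff.or_per_doubling_tmb:
        wide = tmb_table.pivot(index="sample_id", columns="pathway", values="log2_tmb")
        for pw, or_ in eff.or_per_doubling_tmb.items():
            vals = out["id"].map(wide[pw]).to_numpy(dtype=float)
            logit += np.log(or_) * (vals - vals.mean())

    if eff.expr_outcome_effect:
        if expr is None:
            raise ValueError("expr matrix required when expr_outcome_effect set")
        lib = expr.sum(axis=0).to_numpy(dtype=float)
        for g, beta in eff.expr_outcome_effect.items():
            c = expr.loc[g].reindex(out["id"]).to_numpy(dtype=float)
            l2 = np.log2((c + 0.5) / (lib + 1.0) * 1e6)
            logit += beta * (l2 - l2.mean())

    ce = eff.covariate_effects
    if ce:
        logit += ce.get("age_per_decade", 0.0) * (out["age"].to_numpy() - 50) / 10
        logit += ce.get("postmenopausal", 0.0) * (out["menopause"] == "post").to_numpy(float)
        logit += ce.get("stageII", 0.0) * (out["stage"] == "II").to_numpy(float)
        logit += ce.get("stageIII", 0.0) * (out["stage"] == "III").to_numpy(float)

    event = rng.random(n) < expit(logit)
    t_event = rng.uniform(0.0, 5.0, n).round(3)
    out["idfs_event"] = event
    out["idfs_time_years"] = np.where(event, t_event, out["followup_years"])
    out["followup_years"] = np.where(event, t_event, out["followup_years"])
    out["nonbc_death"] = event & (rng.random(n) < 0.08)
    return out


def demo_pathway_collection(
    seed: int = 0,
    sizes: Mapping[str, int] | None = None,
    n_genes: int = 544,
) -> PathwayCollection:
    """Synthetic stand-in for the five neuroendocrine pathway gene sets.

    Five sets with the canonical sizes (236 adrenergic, 153 glucocorticoid,
    138 dopaminergic, 125 serotonergic, 235 cholinergic) drawn over a
    universe of 544 synthetic gene symbols so the overlap structure (sets
    sharing genes) is exercised; coding lengths are uniform on
    [500, 8000] bp.  Gene symbols are synthetic (``NEG####``), not real
    genome annotation.
    """
    if sizes is None:
        sizes = {
            "adrenergic": 236,
            "glucocorticoid": 153,
            "dopaminergic": 138,
            "serotonergic": 125,
            "cholinergic": 235,
        }
    total_slots = sum(sizes.values())
    if total_slots < n_genes:
        raise ValueError("pathway sizes cannot cover the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"NEG{i:04d}" for i in range(1, n_genes + 1)]
    lengths = {g: int(rng.integers(500, 8001)) for g in genes}

    names = list(sizes)
    capacity = {p: sizes[p] for p in names}
    members: dict[str, set[str]] = {p: set() for p in names}
    # first pass: every gene lands in at least one pathway with free capacity
    for g in rng.permutation(genes):
        open_p = [p for p in names if capacity[p] > len(members[p])]
        probs = np.array([capacity[p] - len(members[p]) for p in open_p], float)
        pick = open_p[int(rng.choice(len(open_p), p=probs / probs.sum()))]
        members[pick].add(g)
    # second pass: fill each pathway to size with random extra genes (overlap)
    for p in names:
        pool = [g for g in genes if g not in members[p]]
        extra = sizes[p] - len(members[p])
        if extra > 0:
            members[p].update(rng.choice(pool, size=extra, replace=False))
    return PathwayCollection(
        [
            PathwaySet(
                name=p,
                genes=frozenset(members[p]),
                coding_length_bp={g: lengths[g] for g in members[p]},
            )
            for p in names
        ]
    )


def generate_study(
    coll: PathwayCollection,
    cohort_specs: Sequence[CohortSpec],
    eff: EffectSpec,
    seed: int = 0,
    tissues: Sequence[str] = ("tumor",),
    expression_genes: Sequence[str] | None = None,
) -> SimpleNamespace:
    """End-to-end synthetic study: patients, mutations, TMB, expression,
    outcomes — with per-stage seeds spawned deterministically from ``seed``.

    Returns a namespace with ``patients`` (outcome-filled), ``mutations``,
    ``tmb`` (long table), and ``expression`` (dict tissue -> matrix).
    """
    ss = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    frames = []
    for k, spec in enumerate(cohort_specs):
        spec2 = CohortSpec(**{**spec.__dict__, "seed": (spec.seed + child[0] + k) % 2**31})
        frames.append(generate_patients(spec2))
    patients = pd.concat(frames, ignore_index=True)

    mutations = generate_mutations(patients, coll, eff, seed=child[1])
    tmb_table = compute_tmb(mutations, coll, patients["id"].tolist())

    genes = list(expression_genes) if expression_genes is not None else sorted(
        coll.all_genes
    )
    expression = {
        t: generate_expression(
            patients, mutations, genes, eff, tissue=t,
            seed=child[2] + i, coll=coll,
        )
        for i, t in enumerate(tissues)
    }
    patients = generate_outcome(
        patients, tmb_table, expression.get("tumor"), eff, seed=child[3]
    )
    return SimpleNamespace(
        patients=patients,
        mutations=mutations,
        tmb=tmb_table,
        expression=expression,
        collection=coll,
    )


def write_clinical_tsv(patients: pd.DataFrame, path) -> None:
    patients.to_csv(path, sep="\t", index=False)
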