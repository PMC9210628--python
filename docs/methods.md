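# Methods

This note documents the models implemented in `pathburden`, the synthetic
data generator that backs its tests, and the numerical and design choices
that were genuinely open.

## Study design

Patients are dichotomized on invasive disease-free survival at five years:
a **case** has an iDFS event strictly before 5.0 years; a **control** is
event-free with at least 5.0 years of follow-up; everyone else is
ineligible (censored early, or event at/after five years).  The window is
half-open, [0, 5): an event at exactly 5.0 years is neither case nor
control — it is an event, so it cannot be a control, and it is outside the
early-event window, so it is not a case.  This convention is unit-tested.

Each case is matched 1:1 to a control with the same molecular subtype.
Subtypes follow the St Gallen 2013 surrogate rule from ER, PR, HER2 and
Ki-67, evaluated with three-valued logic so that a rule fires only when the
known fields decide it (ER+/PR− is Luminal B whatever HER2 is; ER+ with
unknown HER2 and low Ki-67 is Unclassified).  The Ki-67 cutoff defaults to
20% and is configurable, since published operationalizations vary.  When a
case's HER2 is unknown, the matching key falls back to the (ER, PR)
combination.  Matching processes cases in a seeded random order and draws
uniformly among unused key-compatible controls — reproducing "randomly
selected" exactly and reproducibly — rather than solving an optimal
assignment; unmatched cases are reported, not fatal.  No caliper is applied
to age or any continuous variable.

## Pathway burden

TMB of a pathway is the count of qualifying mutations in its genes per
megabase of their summed coding length.  The qualifying variant-class list
defaults to the nonsynonymous coding classes (missense, nonsense, nonstop,
frameshift, in-frame indel, splice site, translation start) and is
configurable and logged, since reasonable analyses differ here.  Coding
lengths come from a user-supplied two-column TSV or BED (per-gene interval
lengths summed); the pipeline never derives them from annotation itself, so
the statistic's denominator is always explicit.  A gene in *k* pathways
counts in each of the *k* burdens; `drop_shared_genes` provides the
exclusive-gene sensitivity mode.

For the continuous analysis, zeros are handled by log2(TMB + c) with
pseudocount c = half the per-Mb rate of a single mutation in that pathway —
half the minimal observable burden.  This keeps zeros finite while the
coefficient still reads as an odds ratio per doubling for any sample with
at least one mutation; any fixed pseudocount distorts the "per doubling"
reading near zero, and half-minimum is the smallest-impact conventional
choice.

## Association models

Logistic regression is fit by IRLS (Newton with step-halving), converged
when the largest score component is below 1e-8, capped at 100 iterations.
Rank deficiency is detected up front by pivoted QR and reported with the
offending columns; separation is reported both when iteration diverges and
when the fitted probabilities saturate to the outcome (the score also
vanishes in that case, so convergence alone is not trusted).  Wald
covariance comes from the inverse observed information; CIs use
z = 1.959964, and the same constant recovers standard errors from printed
CI bounds, ln(hi/lo)/(2·1.959964).

Covariate schedules: basic (cohort, subtype), main (+ age continuous,
menopausal status, stage), advanced (+ surgery, chemo, radio, hormonal
therapy).  Categorical covariates keep an explicit "unknown" level instead
of dropping rows; reference levels are cohortA, Luminal A, stage I,
premenopausal, no treatment, and are fixed in code.  Matched pairs are
analyzed *unconditionally* with the matching factor as a covariate (not by
conditional logistic regression); this mirrors reporting cohort-adjusted
ORs with subtype among the covariates.  No multiplicity adjustment is
applied across pathways; the five pathway tests are reported as-is.

Between-cohort heterogeneity uses Cochran's Q with fixed-effect
inverse-variance weights and a χ²(k−1) reference; a helper accepts
(OR, CI) triples so heterogeneity can be recomputed from published tables.

## Expression analysis

TMM normalization follows the trimmed-mean-of-M-values algorithm exactly as
in its reference implementation: reference sample chosen by the 75th
percentile of count/library-size closest to the mean; per-sample factors
from the inverse-variance-weighted mean of gene-wise log2 fold changes
after rank-based double trimming (30% on M, 5% on A, each side); genes with
a zero in either member of a comparison excluded; factors rescaled to
geometric mean one.  Agreement with the reference implementation is frozen
into the test suite at 1e-6 on a negative-binomial fixture.  log2 CPM uses
`log2((count + 0.5) / (effective library + 1) * 1e6)` on effective library
sizes (library × factor).

Cross-cohort pooling applies a ComBat-style empirical-Bayes adjustment:
per-gene batch locations and scales estimated on standardized residuals,
shrunk to parametric priors (normal / inverse-gamma, hyperparameters by
method of moments, fixed-point iteration to 1e-4), and removed.  The
adjuster accepts protected biological covariates in its design and raises
when batch is confounded with them.  The analysis pipeline, however, calls
it **without** the outcome in the design: matching balances case status
across cohorts, so protection is unnecessary, and conditioning the
adjustment on the observed outcome would couple the matrix to the labels
and break the exactness of the downstream permutation test (empirically
visible as non-uniform null P-values).  Within-cohort analyses use
unadjusted log2 CPM.

The pathway test is a global test: T = rᵀXXᵀr/m with r the response
residuals of the covariate-only logistic fit and X the column-standardized
expression of the set's genes (genes absent from the matrix are skipped
and counted; constant genes are dropped).  The default P-value is by
permutation of outcome labels with the covariate model refit per
permutation — implemented as a vectorized Newton solver across all
permutations with per-row step-halving — and P = (1 + #{T_perm ≥ T_obs}) /
(n_perm + 1), which cannot be zero.  An asymptotic alternative
moment-matches T to a scaled chi-squared using exact Bernoulli residual
moments at the fitted probabilities; it ignores covariate-estimation
variability and is offered as a fast approximation, with the permutation
default preferred because its calibration is testable.

## Gene screen and mediation

Within a chosen pathway, each gene is screened on two associations:
expression on the binary burden flag (OLS) and outcome on expression
(logistic), both covariate-adjusted.  "Empirical P" is a permutation P of
the exposure of interest with full refitting (10,000 draws by default;
study code uses fewer), since the term is otherwise underspecified; an
asymptotic mode gives Wald P-values instead.  A gene passes when both
P < 0.05.

The proportion mediated uses the difference-of-coefficients method on the
log-odds scale: total (without the gene) minus direct (with it), over
total, with a percentile bootstrap over samples for the CI.  The odds
ratio is non-collapsible, so total ≠ direct + indirect exactly in general;
the difference method is nevertheless the minimal estimator consistent
with reporting a single percentage, and it preserves sign — negative
proportions (indirect path opposing the direct one) are reported, not
clipped.  When |total| < 1e-6 the proportion is undefined and reported as
such.

## Synthetic data generator

The generator emulates what the pipeline consumes, with the causal
structure under study built in:

* **Covariates** per cohort: age normal (default mean 54, SD 13, clipped
  23–90); menopause logistic in age around 50 with a 6% unknown rate;
  subtype drawn from configurable probabilities (defaults ≈ 21/40/19/12/8%
  for Luminal A/B, TNBC, HER2, Unclassified) with receptors and Ki-67
  drawn *consistently with the classification rule* (Unclassified patients
  get unknown HER2); stage ≈ 15/55/30%; treatment indicators with ~10%
  unknown.  Follow-up uniform on 1–10 years so the ineligible paths
  (censored before five years) are exercised.
* **Mutations**: per-pathway count ~ Poisson(rate × coding Mb), genes hit
  with probability proportional to coding length, variant classes from a
  fixed nonsynonymous mix.  The default rate of 0.5/Mb yields any-mutation
  prevalences of roughly 0.35–0.65 across the five demo pathways
  (overlapping sets inflate each other), the range seen in pathway-level
  breast-cancer burden data.
* **Expression**: negative-binomial counts (single dispersion, default
  0.3), per-sample log-normal depth, per-gene baselines hashed from the
  gene symbol (stable across tissues and calls), an additive per-cohort
  log2 batch shift (default 0.5 on cohortB), and — in tumor tissue only —
  a configurable log2 shift in samples whose pathway is mutated.  Normal
  tissue never receives mutation effects.
* **Outcome**: the five-year event is drawn directly from a logistic model
  (the design dichotomizes at five years, so no hazard model is needed):
  logit = baseline + Σ ln(OR per doubling)·log2TMB + Σ β·log2CPM
  (centered) + covariate effects.  Event times are uniform on (0, 5);
  a small fraction of events are flagged non-breast-cancer deaths for the
  sensitivity-exclusion path.

Everything is deterministic given seeds, with per-stage seeds spawned from
one root.  The demo pathway collection has five sets of sizes
236/153/138/125/235 over 544 synthetic gene symbols (`NEG####`) with
uniform 500–8000 bp coding lengths; it is a synthetic stand-in, not genome
annotation.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: gene–gene expression correlation beyond
shared depth, tumor purity and subclonality, driver/passenger structure in
mutations, batch effects beyond location shifts, informative censoring,
and real St Gallen edge cases beyond the published rule.  Tests validate
the statistical machinery, not biology.

## Operating characteristics measured

The `studies` module runs the full chain against known truth; the test
suite asserts, and `scripts/acceptance.py` re-measures, the following (the
problem sizes are the package's own choices for single-CPU runs):

* **Null calibration** of the permutation global test — two cohorts of
  200, all effects zero, 1000 replicates of 500 permutations: rejection at
  the nominal 5% and uniform P-values (KS).
* **Tumor/normal discrimination** — outcome effects on 20% of the test
  pathway's genes (0.4 log-odds per log2 unit), 200 replicates: the
  tumor-tissue test rejects in ≥ 90% while normal tissue stays nominal.
* **OR recovery** — true OR 1.5 per doubling, 200 studies of 2000
  patients: 95% Wald CI coverage at its nominal rate.
* **Mediation recovery** — full-mediation, null-gene and
  opposing-indirect constructions at n = 5000: proportion ≈ 1, ≈ 0, and
  negative, respectively.

## Known limitations

Unconditional (not conditional) logistic analysis of matched pairs;
fixed-effect heterogeneity only (no random-effects pooling); the
asymptotic global-test P ignores covariate-estimation variability;
difference-method mediation inherits odds-ratio non-collapsibility; the
permutation engines assume exchangeability of outcome labels given
covariates, which matched sampling satisfies here but informative
selection in real data may not.
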