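# pathburden

Pathway-level tumor mutation burden and expression association analysis for
matched extreme case–control cancer-prognosis studies.

## The problem

Does a higher somatic mutation burden in a candidate gene set (for example
the neuroendocrine signalling pathways in breast cancer) predict worse
invasive disease-free survival (iDFS), and is that association carried by
dysregulated expression of the same genes in tumor tissue?  Answering this
on real cohorts involves a chain of design and statistical steps that are
easy to get subtly wrong: an extreme case–control design dichotomized at
five years, 1:1 matching on molecular subtype, a per-megabase burden
statistic, covariate-adjusted logistic models compared across cohorts, gene
set (global) tests on normalized, batch-adjusted RNA-seq counts, and
mediation screening.  `pathburden` implements that chain as a tested,
reusable library with a synthetic two-cohort generator, so every stage can
be validated against known truth before it ever touches real data.  It is
written for biostatisticians and computational epidemiologists running
pathway-level prognosis analyses.

## The statistics at the core

**Burden.** For pathway *P* with total coding length *L(P)* base pairs and
*m(s, P)* qualifying nonsynonymous mutations in sample *s*,

    TMB(s, P) = m(s, P) / (L(P) / 10^6)   mutations per megabase,

analyzed both as the binary indicator 1{m > 0} and continuously as
log2(TMB + c) with pseudocount *c* equal to half the burden of a single
mutation, so a one-unit effect is an odds ratio *per doubling* of burden.

**Association.** Case status (iDFS event within five years vs event-free
for at least five years) is modelled by unconditional logistic regression
with schedules of adjustment (basic: cohort + subtype; main: + age,
menopausal status, stage; advanced: + treatment).  Cohort-specific
estimates (θ̂₁, θ̂₂) with standard errors are compared by Cochran's Q,

    Q = Σᵢ wᵢ (θ̂ᵢ − θ̄)²,  wᵢ = 1/SEᵢ²,  θ̄ = Σ wᵢθ̂ᵢ / Σ wᵢ,

referred to χ²(k−1).

**Expression.** Counts are TMM-normalized, converted to log2 CPM, and
batch-adjusted across cohorts (empirical-Bayes location/scale).  The
pathway-level test is a global test: with μ̂ the fitted probabilities of
the covariate-only logistic model, r = y − μ̂, and X the column-standardized
expression of the set's genes,

    T = rᵀ X Xᵀ r / m,

with significance by permutation of outcome labels (covariate model refit
per permutation).

**Mediation.** Genes passing a dual screen (burden→expression by linear
regression and expression→outcome by logistic regression, both with
permutation "empirical" P < 0.05) are assessed by the difference method:
proportion mediated = (total − direct)/total on the log-odds scale, with a
percentile bootstrap CI; negative proportions (inconsistent mediation) are
reported as such.

## Worked example

The bundled demo configuration simulates two cohorts of 300 patients with a
glucocorticoid-pathway burden effect (OR 1.5 per doubling) and a
burden→expression→outcome chain on two genes, then runs every stage:

```sh
pathburden all --seed 11 --outdir demo_out
```

or in Python:

```python
from pathburden.pipeline import run
run(seed=11, outdir="demo_out")
```

`demo_out/assoc.tsv` contains the adjusted odds ratios (Table-2-style):

```
pathway         exposure  cohort   n_cases n_controls odds_ratio ci_low ci_high  p_value   p_heterogeneity
glucocorticoid  log2_tmb  pooled   179     179        2.83       2.15   3.72     8.2e-14   0.62
glucocorticoid  log2_tmb  cohortA  89      97         2.69       1.83   3.96     4.9e-07
glucocorticoid  log2_tmb  cohortB  90      82         3.11       2.06   4.70     7.0e-08
```

The pooled OR per doubling (2.83) exceeds the configured direct effect of
1.5 because the demo also routes signal through the two expression-effect
genes; the heterogeneity P of 0.62 says the two cohorts agree.
`demo_out/globaltest.tsv` shows the tumor/normal contrast — the pathway
carrying the simulated expression signal is detected in tumor but not in
the mutation-blind normal tissue:

```
pathway         tissue  p_value
glucocorticoid  tumor   0.0020
glucocorticoid  normal  0.5269
```

and `demo_out/mediation.tsv` reports, for the two genes that pass the dual
screen, the proportion of the burden–outcome association each mediates:

```
gene     total_effect direct_effect proportion_mediated ci_low ci_high
NEG0002  1.913        1.051         0.451               0.303  0.696
NEG0008  1.913        1.468         0.233               0.139  0.424
```

The library surface mirrors statsmodels: `PathwayAssociationModel(...).fit()`
returns a results object with `.summary()` and `.plot_forest()`;
`GlobalTest(...).fit()` and `MediationModel(...).fit()` follow the same
pattern.

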