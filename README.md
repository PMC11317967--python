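# aied — A-to-I RNA editing analysis

`aied` is a Python library (with a thin `aied` command-line wrapper) for
transcriptome-wide analysis of adenosine-to-inosine (A-to-I) RNA editing
from RNA-seq allele counts. A-to-I editing — enzymatic deamination of
adenosine in double-stranded RNA — reads as A>G mismatches in sequencing
data; the package takes per-site, per-sample counts of unedited (A) and
edited (G) reads and carries them through a complete differential-editing
study: high-confidence site cataloguing, editing-level quantification,
group comparisons with covariates, temporal trend classification,
editing-expression integration, cross-dataset comparison and
treatment-rescue screening. It is aimed at researchers who already have
variant-level calls (e.g. from a VarScan/VEP-style pipeline) and need the
downstream statistics, and it ships a fully seeded synthetic-study
generator with ground truth for validating every step.

## The statistics at the core

* **Editing level** at a site in a sample: `phi = alt / (ref + alt)`,
  treated as missing below a coverage floor (default 10 reads).
* **High-confidence catalog**: a candidate A>G site is retained iff it is a
  known editing site (REDIportal-style whitelist) *or* its mean level in at
  least one design subgroup is >= 5% and editing (>= 1 edited read at
  adequate coverage) is observed in >= 2 samples.
* **Differential editing (DRE)**: per site, a binomial GLM with logit link
  on per-sample (alt, ref) counts; the likelihood-ratio test of the group
  factor gives `P_GLM ~ chi2(K-1)`. Sites with `P_GLM < 0.05` receive a
  confirmatory 2 x K exact test on group-pooled allele counts
  (`P_Fisher`; Freeman-Halton by exact enumeration for K > 2). The call is
  `BH-FDR(P_GLM) < 0.05 AND P_Fisher < 0.05`; a no-FDR mode supports
  cross-dataset intersection. Age and sex covariate p-values come from 1-df
  LRTs dropping each factor from intercept + group + age + sex.
* **Integration**: TPM normalization, negative-binomial GLM + LRT for
  differential expression, Spearman rank correlation for per-site
  cis-regulatory editing-expression association, Venn decomposition of DRE
  sets across datasets, and a three-condition rescue rule for
  pre-treatment designs.

The synthetic generator draws coverage `n ~ max(1, Poisson(mu))` and edited
reads `alt ~ BetaBinomial(n, p, rho)` with additive, clamped group/age/sex
shifts on the proportion scale and editing-coupled log-normal gene
expression — the exact structure the estimators above assume.

## Worked example

`examples/02_differential_editing.py` simulates the default 48-sample
three-group design (control and days 1 and 4 after a septic insult, split
by age and sex) with 20% of 300 sites truly shifted by +0.10, then runs the
full two-stage caller:

```
tested 296 sites; called 74 DRE (sensitivity 0.97, null call rate 0.068)
a DRE call requires BH-FDR(P_GLM) < 0.05 AND pooled Fisher P < 0.05

temporal trends among DRE calls:
trend
early_up_then_down    33
late_up               29
down                  12

age / sex covariate p-values (GLM dropping one factor at a time):
  Gene0063:chr7:38300825: P_age=0.5663  P_sex=0.1780
  Gene0174:chr11:20578846: P_age=0.4687  P_sex=0.0268
  ...
```

Reading the output: 74 of 296 tested sites pass the two-stage rule, which
recovers 97% of the truly shifted sites; the trend labels classify each
call's trajectory over the two post-insult time points (transiently up,
late-rising, or persistently down); and the covariate p-values flag sites
whose editing differs by age or sex after accounting for group. The other
examples cover catalog construction and repeat annotation (`01`),
expression integration (`03`), and cross-dataset overlap plus rescue
screening (`04`); each prints the numbers it computes and one line on what
they mean.

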