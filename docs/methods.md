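# Methods

`aied` implements a transcriptome-wide analysis of adenosine-to-inosine
(A-to-I) RNA editing from per-site allele counts: catalog construction,
editing-level quantification, differential-editing statistics with age and
sex covariates, temporal trend classification, editing-expression
integration, cross-dataset comparison and treatment-rescue calling, plus a
synthetic-data generator that reproduces the statistical structure these
methods assume. This note records the model, the defaults and the design
choices a maintainer would want to know.

## Input model and coordinate conventions

The pipeline starts at per-(site, sample) allele counts: `ref_count`
unedited (A) reads and `alt_count` edited (G) reads at a genomic position.
Candidate calls are canonicalized to the sense strand before anything else:
A>G on `+` is kept, T>C on `-` is the same editing event read antisense and
is rewritten to A>G, every other substitution is discarded as not A-to-I,
and a T>C call without a usable strand is an error rather than a guess.
Allele-count and known-site tables use 1-based positions; the repeat BED is
0-based half-open, and the conversion lives in exactly one place
(`overlap_repeats`: a site at 1-based `p` hits `[start, end)` iff
`start <= p-1 < end`, ties going to the first interval in file order).
Known-site lookup is exact on (chrom, pos) and deliberately ignores strand,
because public catalogues store sense-oriented records and candidates are
canonicalized first. Functional consequences and gene assignments are
consumed as an annotation input, not recomputed.

## High-confidence catalog

A candidate site is retained iff it is a known editing site, **or** its mean
editing level within at least one design subgroup (group x age x sex cell)
is >= 5% (inclusive) **and** editing is observed in at least two samples
study-wide. "Observed" means >= 1 edited read at >= `min_coverage` total
reads; the coverage floor (default 10 reads, applied identically to level
computation) keeps single-read artefacts and near-zero-coverage ratios out
of every average. Subgroup means skip samples below the floor; a subgroup
with no covered samples contributes nothing rather than a NaN. The
two-sample observation rule is counted study-wide, not within the
qualifying subgroup. The filter is monotone: relaxing the threshold or the
sample rule can only grow the catalog.

## Editing levels and sample summaries

The editing level is `alt / (ref + alt)`, missing below the coverage floor.
Sample-wide average editing is the unweighted mean over non-missing catalog
sites (unbiased if coverage dropout is unrelated to level; sites are not
coverage-weighted). Per sample we also count edited sites (level > 0 at
adequate coverage) and edited genes, and report the Pearson correlation of
average editing with both counts. A one-way ANOVA with Tukey HSD on the
per-sample means is provided as a descriptive convenience only.

## Differential editing

Per site, a binomial GLM with logit link is fitted to the per-sample
(alt, ref) counts with group as a factor; the likelihood-ratio test of the
group term against the reduced model gives `P_GLM` (chi-square,
`#groups - 1` df). Sites with `P_GLM < 0.05` get a confirmatory exact test
on the 2 x K table of allele counts pooled within groups (`P_Fisher`).
`P_GLM` is Benjamini-Hochberg adjusted across tested sites, and the DRE
call is `FDR < 0.05 AND P_Fisher < 0.05`. Only sites with >= 5% mean
editing in at least one subgroup are tested. A cross-dataset mode calls at
raw `P_GLM < 0.05` with no FDR step, the appropriate behaviour when
intersecting independently processed datasets, where FDR correction inside
each dataset would over-correct the comparison.

Implementation notes:

* Sites with no edited (or no unedited) read anywhere carry no information
  about the group factor; they return p = 1 with a flag instead of raising.
* K = 2 pooled tables use the standard two-sided hypergeometric test; K > 2
  uses the Freeman-Halton extension computed by exact enumeration of all
  margin-constrained tables in log-gamma arithmetic, summing tables no more
  probable than the observed one (probability-ratio tie gate 1 + 1e-7).
  Past an enumeration budget of 5e6 tables the p-value is estimated by
  seeded Monte-Carlo over the multivariate hypergeometric null (1e5 draws,
  add-one estimator); at typical pooled depths the exact path always runs.
* BH adjustment is the standard step-up transform with cumulative-minimum
  monotonicity, capped at 1, NaN entries excluded and reinserted.

**Overdispersion.** Biological replicates are overdispersed relative to the
binomial: with intra-class correlation `rho` and coverage `n`, proportions
have variance inflated by `1 + (n-1) rho`. The binomial LRT ignores this
and is anti-conservative (at `rho = 0.01`, coverage ~50, the nominal 5%
group test rejects ~13% of null sites), and the pooled exact test inherits
essentially the same inflation because for a group-only model the binomial
LRT is algebraically the G-test on the same pooled table — the confirmation
stage therefore removes few overdispersion-driven false positives. The
default remains the plain binomial LRT, matching the stated two-stage
procedure; a quasi-binomial mode (`dispersion="quasi"`) rescales the LRT by
the full model's Pearson dispersion and refers it to an F distribution,
which restores calibration under overdispersion (measured ~5% at
`rho = 0.01`) at a small cost in power. Users analysing real replicates
should prefer it, or rely on the FDR step's partial protection.

**Covariates.** Age and sex enter the same GLM; each covariate's p-value is
the 1-df LRT from dropping it out of intercept + group + age + sex. A
covariate constant across samples is reported as inestimable (NaN). Under
the null these tests are calibrated (measured 5.0-5.2% at nominal 5% across
2000 simulated sites), and a +0.15 proportion-scale age shift at 8 samples
per age is detected with power ~1.0.

**Trends.** Temporal trajectories over (control, D1, D4) are classified by
rule, transcribing the three observed archetypes, rather than by
unsupervised clustering for which there is no stated algorithm:
`early_up_then_down` iff mean(D1) > mean(control) and mean(D4) < mean(D1);
`late_up` iff mean(D4) > mean(control) and mean(D4) >= mean(D1); `down` iff
both post-baseline means are below control; anything else (including exact
ties that satisfy no strict rule) is `unclassified`. Labels are assigned
only to DRE calls.

## Expression integration

TPM per sample is `1e6 * (count/length) / sum(count/length)`; columns sum
to 1e6 by construction and the normalization is invariant to rescaling all
lengths. Differential expression uses a log-link count GLM with a
log-library-size offset and an LRT on the group term; the default family is
negative binomial with a per-gene method-of-moments dispersion estimated
from a Poisson pilot fit (clipped to [1e-8, 10]), because RNA-seq counts
are overdispersed; a Poisson family is available as a config knob.
Single-sample groups are rejected (dispersion inestimable) and all-zero
genes are skipped with a flag. Cis-regulation is tested per site with
Spearman rank correlation (mid-ranks, two-sided p) between editing level
and the host gene's TPM across samples, requiring >= 5 complete pairs — a
deliberately assumption-light monotone-association test.

Cross-dataset comparison computes all `2^k - 1` Venn cells of named DRE
site-id sets (duplicates de-duplicated with a warning), plus the
convenience counts "shared by all" and "in set A and at least one other".
Site ids are assumed to share one genome build; nothing beyond chrom/pos
equality is checked.

**Rescue.** In a three-arm design (control, insult, pre-treated insult) a
site is rescued iff insult vs control is significant (two-group GLM + LRT,
p < 0.05), pre-treated vs insult is significant in the opposite direction,
and the pre-treated mean lies closer to control than the insult mean does.
This operationalizes "restored toward control"; each clause is explicit so
alternative rules can be composed from the same primitives.

## Synthetic-data generator

The generator emulates the study design the analysis assumes: by default a
three-group longitudinal design (control/D1/D4) stratified by age (young,
old) and sex (male, female), four replicates per cell (48 samples).
Defaults, with rationale:

| parameter | default | meaning |
|---|---|---|
| `coverage_mean` | 50 | mean Poisson reads/site/sample, floored at 1; gives realistic missingness when thinned |
| `dispersion` (rho) | 0.01 | beta-binomial intra-class correlation; 0 degenerates to binomial |
| `effect_size` | 0.10 | additive group shift on the proportion scale (ten percentage points) |
| `baseline_level_range` | (0.02, 0.40) | uniform baseline editing levels |
| `frac_dre` | 0.20 | sites with a true group effect |
| `frac_known` | 0.30 | sites present in the known-site whitelist |
| `frac_age_effect`, `frac_sex_effect` | 0.05 | sites with covariate shifts (+0.10 by default) |
| `coupling` | 2.0 | log-expression slope per unit editing level at coupled genes (`frac_coupled` = 0.25) |

Effects are additive on the proportion scale with clamping into
[0.001, 0.999] — not logit-scale — because differential editing is
described and thresholded in percentage points; clamping means a -0.10
shift on a 0.02 baseline realizes as -0.019, and recovery checks compare
against the clamped truth. Sites with a group effect receive one of three
trend archetypes (early-up 50%, late-up 30%, down 20%, mirroring the
largest/moderate/smallest observed clusters). The consequence categories of
simulated sites are drawn with weights proportional to the published
hippocampal catalog composition (3'UTR-dominated), repeats are B1-heavy,
and minus-strand sites are written antisense (T>C) to exercise the
orientation step. Coupled genes draw log-normal counts whose log-mean is
shifted by coupling x realized editing level, making the cis rank
correlation recoverable. Everything flows through one seeded generator:
identical configs give byte-identical studies.

What the generator does **not** emulate: alignment and mapping artefacts,
strand-library protocols, position-dependent coverage, hyper-editing
clusters, ADAR expression dynamics, correlated sites within a repeat, or
coverage-driven correlation between a sample's average editing and its
number of detected sites. Passing the recovery tests therefore shows the
statistics behave correctly under their own assumptions, not that those
assumptions hold in any real library. In particular, the observed positive
correlation between average editing and edited-site counts in real data is
partly a detection-depth phenomenon that this generator deliberately lacks,
so the synthetic analogue of that correlation hovers near zero.

## Problem sizes and numerical choices

The seeded simulation checks use 2000 null sites for type-I error, 500
sites (20% with +0.10 effects) for two-stage power and effect recovery,
200/1000 replicates for covariate power/calibration, and ~100-site
three-arm studies at coverage 100 for rescue operating characteristics —
sizes at which the Monte-Carlo error of each measured rate is comfortably
inside the asserted bands. Effect-recovery is asserted as mean absolute
error (<= 0.03) across shifted sites, since the per-site Monte-Carlo s.e.
of a group-mean difference at 16 samples x 50 reads is ~0.015. The
acceptance checks assert the binomial pipeline's null calibration both at
`rho = 0` (within 0.04-0.06) and at `rho = 0.01` (bound 0.08); the latter
documents the overdispersion anti-conservativeness discussed above and
fails by construction for the default binomial mode — it is retained as a
known limitation rather than silently switching the default to the quasi
mode.

GLM fits run IRLS to tolerance 1e-10 (max 100 iterations); non-convergence
and separation are reported per site as missing p-values with a reason,
never as exceptions. The hand-coded IRLS oracle used in tests is
independent of the statsmodels fitting path and agrees to < 1e-6 in
deviance and p-value on 50 random fixtures.

## Known limitations

* The binomial default is anti-conservative under replicate overdispersion
  (see above); the quasi mode is provided but not default.
* The DRE composition rule (FDR on `P_GLM` combined with raw `P_Fisher`) is
  one reasonable reading of a two-stage procedure whose exact composition
  is underdetermined; both statistics and the FDR are emitted per site so
  other compositions can be applied downstream.
* Covariate effects apply to the last listed factor level and are shared
  across groups (no group x age interactions are simulated or tested).
* The negative-binomial DE test uses a moment dispersion estimate per gene;
  it is a plain GLM + LRT, not a shrinkage estimator, and is less powerful
  than dedicated DE packages at small n.
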