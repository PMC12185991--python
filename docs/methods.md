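# Methods

`dysbiome` re-implements, as a tested and reusable pipeline, a cohort
analysis linking the gut microbiome of people with HIV (PWH) to lung
function: starting from a species-level relative-abundance table and
clinical metadata, it derives spirometry outcomes, runs diversity and
covariate-adjusted differential-abundance analyses, constructs a microbial
dysbiosis index with a Mann-Whitney pruning rule, and estimates adjusted
odds ratios (aORs) for rapid lung-function decline and airflow limitation.
Because cohort metadata of this kind are typically access-restricted, the
package ships a synthetic-cohort generator that emulates the data structure
and provides ground truth for recovery testing.

## Outcomes

* **Rapid lung-function decline** (primary): FEV1 loss strictly greater
  than 40 mL/year, computed as `(FEV1_baseline − FEV1_followup) /
  followup_years`. Undefined (missing) when follow-up spirometry is absent.
* **Airflow limitation** (secondary): FEV1/FVC < 0.70 **and** FEV1 < 80% of
  the predicted value (moderate-or-worse obstruction). Percent-predicted
  FEV1 is consumed as a given metadata column; no reference-equation
  computation is performed.

Both rules are strict inequalities; a decline of exactly 40 mL/year is not
rapid, and FEV1/FVC = 0.65 with 85% predicted is not airflow limitation.

## Data model and normalisation

Abundances are MetaPhlAn-style percent profiles (rows sum to ≤ 100;
pipe-delimited lineages with `k__`/`d__` … `s__` prefixes). Negative-binomial
(NB) modelling needs integers, so percent profiles are converted to
pseudo-counts at a fixed per-sample depth (default 100 000), which makes
size factors interpretable. Taxa present in fewer than 10% of samples
(configurable) are excluded from differential abundance and index
construction; rare-taxon NB fits are unstable.

## Diversity

Shannon (natural log) and inverse Simpson indices per sample, compared
between groups with the Mann-Whitney U test. Beta diversity is Bray-Curtis
on the raw percent values; ordination is classical PCoA (Gower
double-centering of −½d², eigendecomposition; negative eigenvalues are kept
in the spectrum but yield no coordinates, and proportion explained is over
positive eigenvalues only). PERMANOVA uses the sequential (terms-in-order)
partition of the Gower-centred sum of squares with covariates entered
before the group term — the adonis2-style adjustment — and p-values from
free permutation of sample identities (999 permutations by default). A
random permutation occasionally maps the group partition onto itself and
then ties the observed pseudo-F exactly; the permutation p-value counts it,
as it should.

## Differential abundance

A compact re-implementation of the standard NB Wald workflow:

1. **Size factors** — median-of-ratios over taxa with nonzero counts in
   every sample, normalised to geometric mean 1; if no such taxon exists,
   geometric means over positive counts only (logged).
2. **Dispersions** — per-taxon NB maximum likelihood profiled on a
   log-spaced grid (56 points in [1e-8, 40]) with quadratic refinement,
   given means from a vectorised IRLS fit; a parametric trend
   `alpha(mu) = a0 + a1/mu` fitted across taxa by Gamma GLM; a final
   posterior mode shrinking the taxon-wise estimate toward the trend under
   a log-normal prior (variance 0.25, configurable). Taxa whose ML estimate
   exceeds the trend by more than two prior SDs keep their own estimate
   (outlier protection) — shrinking a genuinely high dispersion would
   inflate the Wald statistic.
3. **Wald test** — NB GLM (log link, size-factor offsets) on
   `[intercept | smoking dummies | condition]`, with "never" smoking as
   reference; the condition coefficient is reported as log2 fold change,
   z = coefficient/SE, two-sided normal p, BH-adjusted within the tested
   rank. No independent filtering and no fold-change shrinkage.

All per-taxon fits share the design matrix, so IRLS and the dispersion grid
are vectorised across taxa; a full 350 × 400 cohort takes well under a
second. Non-converged taxa (|coef| ≥ 30 on the natural-log scale or
non-finite) are flagged and excluded from the BH family.

Numerical notes: the NB score equation with per-sample offsets is exactly
scale-equivariant only at dispersion 0 (Poisson); with dispersion > 0,
multiplying all counts by a constant perturbs coefficients at the 1e-3
level. The scale-invariance guarantee therefore applies to the Poisson
limit, which is how it is tested.

## Dysbiosis index

Significant species (BH < 0.05) are split by fold-change sign into
increased/decreased sets, then pruned: each candidate's abundances are
compared between outcome groups by Mann-Whitney U, and taxa with p > 0.10
are removed (taxa at exactly 0.10 are retained). The index per sample is

    log10(sum of increased abundances + pc) − log10(sum of decreased abundances + pc)

with pseudocount `pc` defaulting to half the smallest nonzero abundance in
the table (standard compositional practice; keeps the index finite when a
sample has none of the decreased taxa, and recorded in every output).
Computing the difference of logarithms rather than the log of the ratio
makes antisymmetry under set exchange bitwise exact. The index is
constructed on the rapid-decline contrast and applied unchanged to the
airflow-limitation association. If either set is empty before or after
pruning the index is undefined and the pipeline stops with an explanatory
status.

The Mann-Whitney test is exact by enumeration of all
`C(n_x + n_y, n_x)` label assignments when `n_x + n_y ≤ 12` (valid under
ties), otherwise a tie-corrected normal approximation with continuity
correction.

## Association models

Logistic regressions are maximum-likelihood fits (IRLS) with Wald SEs from
the observed information; perfect separation raises an error naming the
offending term rather than being silently corrected. The index enters
untransformed (per unit of log10 ratio). For rapid decline: **model 1** =
index + smoking + age + sex + BMI + ethnicity + transmission mode + nadir
CD4 < 200 + HIV duration; **model 2** = model 1 + IL-1β + IL-10;
sensitivity refits of model 1 on the pneumonia-free and grade-A-C
(high-quality spirometry) subsets. For the rarer airflow outcome, one
parsimonious fit per extra covariate: index + age + BMI + one of {smoking,
HIV duration, cART years}. Samples missing any required covariate are
dropped from that model only (n_used reported), never imputed. 95% CIs are
Wald intervals `exp(coef ± 1.96·SE)`.

## Correlation networks

Spearman rank correlations (midrank ties; exact permutation p when n ≤ 9,
t-approximation otherwise) among the top-50 most abundant taxa plus the
index taxa, within each outcome group. Edges require rho > 0.5 (signed, as
the positive-correlation rule; an |rho| option exists) and raw p < 0.05 —
deliberately liberal, with no multiple-testing correction, as a descriptive
display. Long-form taxa × clinical-parameter correlation tables use the
same test.

## Synthetic cohort generator

The generator emulates the study's structure: ~350 samples, ~44.7% rapid
decliners among those with follow-up, ~10% airflow limitation, 400 species,
6 planted enriched and 2 planted depleted species at |log2FC| = 1,
smoking-outcome confounding (OR 1.5 for current smoking), and ~10% missing
follow-up spirometry.

Generative model, in order:

1. Per-taxon baseline log-intensities are normal with SD 2.0 — a heavy
   right tail across taxa, so a few species dominate as in real gut
   metagenomes. Each sample multiplies every taxon by an independent
   mean-one **gamma** factor (shape 1/`bio_dispersion`, default 1.0),
   giving between-subject variation spanning orders of magnitude while
   keeping marginal counts NB-compatible. A log-normal noise mode is
   available via config; its tails are heavier than any NB fit can absorb
   and make ML-based NB Wald tests anticonservative, so it is not the
   default.
2. Planted taxa are drawn from the 50th-90th abundance percentile window:
   abundant enough to be detectable at the sequencing depth, not so
   dominant that closure distorts the rest of the composition.
3. A per-sample *true dysbiosis index* is computed from the pre-effect
   intensities of the planted taxa. Outcome labels are Bernoulli with
   logit = b0 + ln(1.5)·current-smoker + ln(1.2)·(index − mean), the
   intercept solved so the realised prevalence matches the target. Airflow
   labels are drawn the same way at 10% prevalence. Tying the outcome to
   the *pre-planting* index gives a well-defined generative odds ratio that
   the association stage can recover exactly, while the hard fold-change
   applied next gives the differential-abundance stage a well-defined
   effect size to recover; a single mechanism cannot serve both purposes,
   because a ±1 log2 shift in every case makes the observed index a strong
   classifier whose implied per-unit aOR is far above the generative slope.
4. Cases' planted taxa are multiplied by 2^(±1); a set of 10 non-planted
   taxa is shifted in current smokers (so smoking adjustment is
   non-trivial); compositions are renormalised; reads are drawn
   multinomially at depth 100 000 and expressed as percentages (rows sum to
   100 exactly).
5. Spirometry is drawn consistently with the labels (rapid decliners get
   FEV1 slopes in (40, 120] mL/year, others in [−20, 40); airflow cases get
   FEV1/FVC < 0.70 and < 80% predicted); remaining covariates (age, sex,
   BMI, ethnicity, transmission mode, nadir CD4, HIV and cART duration,
   IL-1β, IL-10, pneumonia history, spirometry grade) are drawn from
   distributions matched to the emulated cohort's summary statistics and
   are outcome-independent by design, so adjusting for them is testable but
   not required for validity.

The null generator zeroes every effect (fold changes, smoking odds, index
slope, smoking-taxa shifts) and emits an empty planted truth; it underlies
the type-I-error suites.

What the generator does **not** emulate: taxon-taxon ecological
correlations (taxa are independent given the planted structure), multiple
body sites or time points, batch effects, variable sequencing depth, and
the unclassified fraction. Passing recovery tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to every feature of real metagenomes.

## Problem sizes and numerical choices

The simulation suites use 200 null replicates (full n=350 × 400 cohorts)
for calibration and 50 seeded cohorts for recovery; PERMANOVA calibration
uses 199 permutations per replicate and single-run analyses use 999. IRLS
converges at max |Δcoef| < 1e-9 (cap 60 iterations); logistic fits at the
statsmodels IRLS default with tol 1e-10; dispersion bounds are
[1e-8, 40]. Exact-test thresholds: Mann-Whitney enumeration at pooled
n ≤ 12, Spearman permutation at n ≤ 9. All randomness flows from one root
seed; the pipeline derives stage seeds as `(root·1009 + stage) % 2^31`.

## Known limitations

* The NB Wald test assumes NB-distributed counts; on heavier-tailed data
  (e.g. log-normal noise) it is anticonservative, as the generator's
  alternative noise mode demonstrates.
* The dysbiosis index depends on a pseudocount when decreased-set
  abundances vanish; values are comparable only at a fixed pseudocount.
* Edge rules in co-occurrence networks are uncorrected for multiplicity.
* Percent-predicted FEV1 and spirometry quality grades are taken at face
  value from metadata.
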