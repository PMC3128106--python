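# Methods

## Scope and model

`lipidgen` analyzes candidate-SNP associations with three fasting lipid
traits — HDL-C and LDL-C in mg/dl and triglycerides on the natural-log scale
(lnTG) — in multi-population cohort collections, and classifies whether
associations discovered and replicated in a European-American (EA) reference
generalize to other populations. The genetic model is additive throughout: a
participant's trait is regressed on the 0/1/2 count of the coded allele, so
β is the mean trait change per additional allele copy.

### Trait harmonization

LDL-C is derived by the Friedewald equation, LDL = TC − HDL − TG/5, and set
missing when TG > 400 mg/dl, where the equation is unreliable. TG is
ln-transformed before analysis. Analysis exclusions, applied in a fixed
order with each removed participant charged to the first triggered rule:
age < 18 years; fasting < 8 hours; TG > 1000 mg/dl (lnTG analysis only);
optionally, lipid-lowering-medication use. All boundary cases are retained
(age 18.0, fasting 8.0 h, TG exactly 400 or 1000 are kept) — the exclusion
rules are strict inequalities. Medication adjustment is a subtraction of a
user-supplied per-trait average treatment effect from treated participants'
values; the package deliberately does not estimate these offsets, since they
are drug-class properties external to any one cohort.

### Association and pooling

Per-stratum fits are ordinary least squares on a design of intercept,
genotype dose and model covariates (model 1 none; model 2 age + sex; models
3–4 the fuller covariate sets, fitted within sex strata because menopause
and hormone use are defined for females only; study site optionally enters
as a categorical fixed effect). p-values use the t reference with residual
degrees of freedom, which is exact in small strata. Missing data are handled
by complete-case analysis; monomorphic SNPs are flagged inestimable rather
than erroring, so panels with population-specific fixation still run.

Strata are pooled by fixed-effects inverse-variance weighting: w = 1/SE²,
β̂ = Σwβ/Σw, SE = (Σw)^(−1/2), with the pooled p from the normal reference
(the convention of standard GWAS meta-analysis tools). Heterogeneity is
quantified by Cochran's Q = Σw(β − β̂)² with a χ²(k−1) tail probability and
I² = max(0, (Q − (k−1))/Q)·100, clipped at zero and reported to two
decimals. Heterogeneity is reported but never acted on (no random-effects
fallback), and strata coding different alleles are rejected rather than
silently flipped.

### Replication and generalization

Replication: pooled EA p < α (strict; α = 0.05, uncorrected — the
classification is deliberately liberal because the candidate SNPs carry
strong priors). Generalization: replication in EA *and*, in every
non-European population with genotype data, p < α with the same effect sign
as EA (β = 0 matches no direction). Populations without data are skipped;
with no non-European data at all, a SNP cannot generalize. p-values in
[α, 2α) are tracked as near-misses but never counted. Because one SNP can
be tested for several traits, both tallies are reported: generalized
SNP-trait associations and unique generalized SNPs. On the bundled panel
these differ (17 vs 16) because one SNP generalizes for two traits.

### Power calibration

For the additive model the variance explained is v = 2·caf·(1−caf)·β², and
the two-sided Wald test at level α has non-centrality λ = n·v/(σ² − v),
where σ is the marginal trait SD; power = Φ(√λ − z_{1−α/2}) +
Φ(−√λ − z_{1−α/2}). Residual variance uses the decomposition σ² − v, the
parameterization of standard quantitative-trait power calculators that take
the marginal SD as input; a `marginal_residual` flag substitutes σ² for
users who prefer the cruder form (the difference is negligible for the
per-SNP effect sizes seen in lipids, v ≪ σ²). Summing per-test powers over
a panel gives the expected number of significant tests E, compared with the
observed count k by an exact one-sample binomial test of k/m against
p₀ = E/m. Two-sided by the point-probability method is the default —
it reproduces all nine published observed-vs-expected p-values at printed
precision — and the sidedness is always recorded in output. The exact
reference distribution for unequal per-test powers is also provided: the
Poisson-binomial pmf by dynamic-programming convolution (O(m²), m ≤ 40),
whose tails validate the binomial approximation whenever power dispersion
is small.

### Population structure

Coded-allele-frequency concordance between populations is the Pearson r
over pairwise-complete SNPs of a deduplicated SNP × population panel; a SNP
appearing in several trait tables contributes the mean of its per-table
frequencies after asserting they agree within 0.01. F_ST uses the
two-population Weir–Cockerham variance-components estimator with
HWE-implied heterozygosity h = 2p(1−p), since summary tables carry allele
frequencies, not genotype counts. Sample-size weighting with each
population's maximum analyzed n is the default; an equal-weight variant is
provided because published per-SNP values are not all consistent with one
convention (for the most differentiated SNP in the panel, the weighted form
reproduces the published EA–AA value of 0.15 while the EA–AI value of 0.34
matches the equal-weight form). θ is not truncated, so undifferentiated
pairs can be slightly negative; monomorphic-in-both SNPs are flagged
undefined. LD statistics (D, D′, r²) are computed from four haplotype
counts; a dosage-correlation estimator is included for unphased genotype
vectors (valid under random union of gametes — no EM phasing).

## The synthetic cohort generator

The generator provides individual-level data with exactly the structure the
pipeline assumes, so every stage is testable without access to restricted
cohort data.

- **Genotypes** are Binomial(2, p) draws — Hardy–Weinberg proportions at
  the scenario's coded-allele frequency. Missingness is injected uniformly
  at random at a configurable rate (default 0), after phenotypes are formed.
- **Linked pairs** draw 2n haplotypes from the two-locus table
  {p_Ap_B + D, p_Aq_B − D, q_Ap_B − D, q_Aq_B + D} with
  D = +√(r²·p_Aq_A·p_Bq_B) clipped to the feasible range, then pair them
  into diploids. When the requested r² is infeasible at the given
  frequencies the realized (clipped) value is reported with a warning; note
  that e.g. r² = 0.5 is unattainable for frequencies 0.2 and 0.4, where the
  feasibility bound caps r² at 0.375.
- **Phenotypes**: trait = mean + Σβ·g (mean-centered so the marginal mean
  stays at the scenario value) + optional covariate effects + N(0, σ_e),
  with σ_e² = SD² − Σ2p(1−p)β² − covariate variance, so the marginal SD
  equals the scenario SD; scenarios whose systematic variance reaches the
  trait variance are rejected. TG is simulated log-normally (effects act on
  the ln scale) and exponentiated for storage; TC is constructed as
  LDL + HDL + TG/5 so Friedewald recovers the intended LDL-C wherever it is
  valid.
- **Covariates** (sex, age, BMI, smoking, T2D, menopause/hormone use for
  females, prior MI, fasting hours) are generated independently of
  genotypes and, by default, of traits; a confounding hook lets a covariate
  load on a trait for sensitivity analyses. Default prevalences and moments
  are ordinary US-cohort values (55% female, age ~N(50, 16) truncated to
  include minors so the adult-only filter is exercised, BMI ~N(28, 5), 25%
  smoking, 10% T2D, 5% prior MI, 5% non-fasting). Default trait scales are
  textbook lipid distributions: HDL-C 52 ± 15, LDL-C 122 ± 35 mg/dl, lnTG
  4.79 ± 0.50 (median TG ≈ 120 mg/dl).
- **Medication**: a Bernoulli use flag plus a constant subtractive shift
  per measured channel (HDL-C/LDL-C in mg/dl; TG in mg/dl before the log) —
  a stand-in for drug-class average effects, with no per-class model.
- **Reproducibility**: every variable class draws from its own named
  stream derived from one integer seed, so identical (seed, scenario) gives
  byte-identical tables and adding a SNP or covariate never perturbs the
  other draws.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: family/pedigree structure and cryptic
relatedness (all individuals are unrelated, whereas family cohorts require
kinship adjustment), admixture and ancestry-gradient confounding, survey
weights, genotyping error, assay batch effects, and non-normal trait tails
beyond log-normal TG. Calibration results (type-I error, CI coverage, power
agreement) certify the statistical engine under the generator's clean
assumptions, not robustness to those violations.

## Numerical choices

- OLS is solved by normal equations (X'X is tiny — at most ~10 columns);
  rank deficiency raises an error naming the collinear columns. The
  engine's β/SE agree with an independent reference implementation to
  1e-10 in tests.
- Printed p-values in the bundled panel are stored as text and parsed on
  demand; a printed value below the representable double range parses to
  the smallest positive double and is flagged. Comparisons to α use the
  parsed value and strict inequality; ties at α fail.
- Two betas printed as "<0.001" in the source tables are stored as 0.0005;
  both lie in non-significant cells, so the choice cannot affect any
  classification.
- The two-sided exact tests (binomial and Poisson-binomial) use the
  point-probability method with a 1e-10 relative tolerance for pmf ties.
- Monte-Carlo tolerances in tests are 3 binomial/delta-method standard
  errors around the analytic value.

## Problem sizes

The test suite and acceptance script use simulation sizes chosen to give
stable Monte-Carlo estimates at interactive runtimes: 1,000 replicates of a
3-stratum × 150-participant null chain for type-I error, 500 replicates of
n = 400 for CI coverage, 2,000 replicates per design point for power
calibration on a 6-point grid, n = 50,000 for HWE goodness of fit, and
n = 100,000 haplotype pairs for LD realization. The full suite runs in
about a minute on one core.

## Known limitations

- Only biallelic SNPs, quantitative traits, and the additive model; no
  dominance/interaction power, no binary traits.
- No multiple-testing correction anywhere, by design.
- The EA–AA allele-frequency correlation computed from the bundled
  2-decimal frequencies (r = 0.80) is lower than the value reported from
  the original full-precision frequencies (0.84); the bundled panel cannot
  resolve the difference, and both the convention and the computed value
  are reported by the tooling.
- Which strata entered historical meta-analyses for the sex-stratified
  models is under-documented upstream; `lipidgen` pools all strata flat.
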