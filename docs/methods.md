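# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the limitations of `nagwas`.

## Phenotype model

Coffee consumption enters as an integer count of cups per day.  The
analysis trait is y = log10(cups + 1), which maps 0 cups to 0 and 9 cups
to 1 and tames the strong right skew of consumption counts.  Exclusions:
samples drinking strictly more than `max_cups` (9 for espresso-style
cohorts, 20 for filtered-coffee cohorts, where a cup carries roughly
three times the caffeine) and, by default, samples on hypertensive
medication, who are commonly advised to limit coffee.  Both rules use
strict inequalities ("more than 9" keeps 9).  An optional z-standardization
of the transformed trait exists for sensitivity analysis and is off by
default; all effect sizes in this package are on the log10 scale.

## Mixed model and score test

The per-cohort null model is y = Xβ + g + e with covariates X =
(intercept, sex, age), polygenic effect g ~ N(0, 2K σ²g) and residual
e ~ N(0, I σ²e).  K holds pairwise kinship coefficients with the
self-kinship convention diag(K) = 0.5(1 + f), so 2K gives a duplicate pair
covariance σ²g.  Fitting is REML: with 2K = U diag(d) U′ computed once,
the likelihood profiles analytically over the total variance and is
maximized over h² = σ²g/(σ²g + σ²e) by bounded Brent search on (0, 1)
(tolerance 1e-8), with an explicit boundary check at h² → 0.  When all
eigenvalues of 2K coincide (e.g. K = 0.5 I), V is proportional to I for
every h²; the components are then not separable, the fit is flagged
non-identifiable, and the fixed effects reduce to ordinary least squares.

Each variant is tested in the two-step GRAMMAR/FASTA style: variance
components are estimated once and reused, and the per-variant statistic is
the exact-GLS estimate β̂ = c′V⁻¹y* / c′V⁻¹c, se = (c′V⁻¹c)^{-1/2}, with
V = 2K σ̂²g + I σ̂²e, y* the GLS trait residual and c the coded genotype
residualized on X under the V⁻¹ inner product.  p-values are two-sided
normal, matching the large-sample β/SE reporting convention.  The cached
eigenbasis makes a whole-cohort scan a single matrix product; a dense
matrix-inverse oracle in the tests confirms agreement to 1e-8.  A genotype
with no coded variance after covariate adjustment is flagged untestable and
reported without a p-value.

Genomic kinship is estimated from dosages as K_ij = mean over variants of
(g_i − 2p)(g_j − 2p)/(4p(1−p)), with the diagonal set to 0.5(1 + f̂) using
the standard variant-averaged inbreeding estimate; monomorphic variants are
skipped.  Such a matrix is almost always very slightly indefinite in finite
panels, so the fit truncates negative eigenvalues of 2K at zero by default
(`psd="raise"` restores a hard error).

A practical caveat that shapes the demonstrations in this package: a GRM
estimated from only a few hundred to a few thousand SNPs on a comparable
number of samples is spectrally dominated by Wishart sampling noise, which
attenuates ĥ² and distorts test calibration in either direction depending
on whether the tested variants are inside or outside the panel.  Real
studies estimate K from hundreds of thousands of genotyped SNPs, where this
noise is negligible.  The calibration and two-stage demonstrations
therefore use the pedigree (expected) kinship — the correctly specified
covariance for the simulated trait — while `estimate_kinship` is validated
directly on its own contracts (sib pairs ≈ 0.25, duplicates ≈ 0.5,
unrelated founders ≈ 0).

## Genetic-model coding and filters

Coding is always with respect to allele1, the coded/effect allele;
testing the other allele is an explicit recode.  Additive: the dosage
(0–2).  Recessive: P(hom-allele1); dominant: P(het) + P(hom-allele1) —
read from the imputation genotype probabilities, reducing to 0/1
indicators on hard calls.  The probabilistic (expected-code) choice
generalizes the way dosage generalizes additive coding; a
best-guess-genotype alternative (`recessive_coding="hardcall"`) is
provided.  Filters, all strict comparisons: empirical MAF < 0.01;
imputation INFO < 0.4 (the same field is interpreted as R² with cutoff
0.3 for cohorts imputed with tooling that reports R² — a per-cohort
configuration choice); coded-category frequency < 0.01 or > 0.99, because
a nearly empty (or nearly universal) coded class destabilizes the test.

## Meta-analysis, genomic control, replication

Fixed-effect inverse-variance pooling with weights 1/se²; the arithmetic
is identical for every genetic model, which is precisely why it is
implemented here rather than delegated to additive-only GWAS meta tools.
No heterogeneity statistics are computed by default (Cochran's Q could be
added as a diagnostic).  Genomic control runs on the *pooled* statistics:
λ = median(χ²)/qchisq(0.5, 1); if λ > 1, se ← se·√λ and p is recomputed,
which keeps β/se/p mutually consistent; λ ≤ 1 is recorded but never
inflates significance.  The genome-wide threshold is α/2.2 = 2.27e-8,
with 2.2 the effective number of tests implied by three correlated
genotype codings per variant (taken as an input constant, not re-derived).
A discovery hit replicates when the replication p < α (default 0.05,
strict) and the effect sign is concordant after allele harmonization;
pooling all cohorts should then push p below the discovery value, and that
flag is reported.

## eQTL pattern comparison

Signed scores s = sign(effect)·(−log10 p) keep both strength and
direction; s = 0 when p = 1.  Within an explicit locus window (default:
chr6:107,400,000–107,900,000, the interval between the recombination
hotspots flanking the PDSS2 coffee-consumption signal), GWAS and eQTL
records are matched on (chrom, pos, allele set); a swapped effect allele
flips the eQTL slope sign, and strand-ambiguous A/T and C/G variants are
excluded by default (`--assume-same-strand` overrides, appropriate when
both datasets are aligned to the same reference).  Comparison uses
Kendall's τ-b: the score vectors are far from normal, ranks are the
honest scale, and the tie correction is harmless when ties are absent.
The associated significance test of τ is the single test reported; for
eight or fewer untied pairs the exact permutation null is used instead of
the normal approximation.

## Synthetic cohorts

What it emulates: isolated-population family cohorts at the study's
scale — two discovery cohorts of ~370 and ~843 samples and a replication
cohort of ~1731, built from nuclear families of 2–3 siblings; a recessive
causal variant of effect 0.086 on the log10 scale at coded-allele
frequency 0.548 (coded-homozygote fraction ≈ 0.30); imputation-like
genotype uncertainty with controllable INFO.

Generation: founders draw alleles from Hardy–Weinberg at per-variant
frequencies (uniform on [0.05, 0.5] unless pinned); offspring inherit one
allele per parent by gene dropping, so Mendelian transmission holds
exactly (checked exhaustively in tests).  The latent trait is

    latent = intercept + Σ β_j · code_j(G) + polygenic + sex/age terms + e,

with the polygenic term drawn per family from the pedigree-expected
covariance 2K_ped · σ²g, σ²g = h²/(1−h²)·σ²e.  Defaults: intercept 0.5,
σe = 0.19, h² = 0.4 (inside the 0.36–0.58 twin-study range for coffee
consumption), sex effect −0.03, age effect 0.0015/yr centred at 49, ages
uniform on [18, 80], 5% medicated independent of genotype.  These give a
mean of ≈ 2–3 cups/day with ≈ 9% non-drinkers — a realistic espresso-style
cohort.  Cups are deterministic: cups = round(10^latent − 1) clipped at 0,
a choice that keeps β exactly interpretable on the analysis scale (a
Poisson draw would add dispersion the model never claims).  The rounding
and the floor at zero make the analysed trait a slightly censored version
of the latent one; the measured consequence is a small downward bias
(≈ 0.005–0.007) in recovered recessive effects, well inside the ±0.02
recovery band the tests enforce.

Imputation degradation blends each one-hot genotype-probability triplet
with the Hardy–Weinberg background, (1−a)·onehot + a·(q², 2pq, p²), with
a solved per variant from the empirical dosage variance so the realized
INFO — var(dosage)/(2p̂(1−p̂)), one of several published definitions,
chosen because it needs dosages only — matches the target by
construction.  The blend preserves the allele frequency and is
deterministic; target 1 returns the input untouched.

Matched eQTL patterns: for a chosen fraction of variants the eQTL signed
score is ±(gwas score + N(0, noise)), the rest are null (uniform p, random
slope sign).  With full sharing, no noise and negative sign, τ = −1
exactly; at noise 0.5 and 60 variants, τ concentrates near −0.5, inside
the −0.27…−0.61 range typical of real tissue panels.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: linkage disequilibrium beyond family
co-inheritance (no haplotype structure, so no LD-based fine-mapping
behaviour), population stratification (λ is clean by construction;
genomic control is exercised arithmetically, not against real
stratification), multi-generation pedigrees, X-chromosome dosage, and
genotyping/imputation error beyond the isotropic INFO blend.

## Problem sizes and determinism

The test suite and acceptance script run at deliberately modest sizes
chosen to keep a full run in minutes on a single core: calibration uses 50
null cohorts of n = 1200 with 2000 variants each (100k tests) in the
suite and 12 such cohorts in the acceptance script; effect recovery uses
100 and 30 replicates respectively at n = 1200; the two-stage
demonstration uses 1000 variants per cohort.  At these sizes the λ
estimate from a single scan carries Monte-Carlo noise of roughly ±0.05 —
averages across replicates are the quantities to read.  Every stochastic
path takes an explicit seed; generators derive independent per-stage
streams from (seed, stage) so outputs are bit-reproducible.

## Known limitations

Exact-GLS betas are reported rather than the score-numerator approximation
some two-step implementations use; the two agree to first order but are
not identical.  Fixed-effect pooling only (no random-effects or
sample-size weighting).  Missing dosages are not supported in v1: samples
with missingness at a variant must be dropped before testing.  The 2.2
effective-tests constant is cohort-independent by assumption.  Only
biallelic autosomal variants are handled.
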