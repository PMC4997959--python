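# nagwas — non-additive GWAS in family cohorts

`nagwas` is a Python library for genome-wide association scans of a
quantitative trait under **non-additive genetic models** (recessive and
dominant, alongside the usual additive coding) in **family-structured
cohorts**, with model-agnostic meta-analysis and a signed-score comparison
of an association locus against cis-eQTL patterns.  The motivating use case
is habitual coffee consumption — cups per day, analysed as
log₁₀(cups + 1) — where a recessive locus effect is invisible to a purely
additive scan.

## What it computes

**Per-cohort scan.**  For trait *y* with covariates *X* (intercept, sex,
age) and kinship matrix *K*, the polygenic mixed model

&nbsp;&nbsp;&nbsp;&nbsp;*y* = *Xβ* + *g* + *e*, *g* ~ N(0, 2K·σ²g), *e* ~ N(0, I·σ²e)

is fitted once by REML (one eigendecomposition of 2K, Brent search over
h² = σ²g/(σ²g+σ²e)).  Every variant is then score-tested in the two-step
GRAMMAR/FASTA style against V = 2K·σ̂²g + I·σ̂²e:

&nbsp;&nbsp;&nbsp;&nbsp;β̂ = cᵀV⁻¹y\* / cᵀV⁻¹c, se = (cᵀV⁻¹c)^(−1/2),

with *c* the model-coded genotype residualized on the covariates.  Codings
are additive (allele-1 dosage, 0–2), dominant (P(het) + P(hom)), and
recessive (P(hom)); under imputation uncertainty the non-additive codes are
read directly from the genotype probabilities.  Variants are filtered on
MAF, imputation INFO/R², and the coded-category frequency (< 0.01 or
> 0.99 removed).

**Meta-analysis and replication.**  Fixed-effect inverse-variance pooling
(βₚ = Σwᵢβᵢ/Σwᵢ, wᵢ = 1/seᵢ², seₚ = (Σwᵢ)^(−1/2)) is identical under every
genetic model — the reason standard additive-only meta tools don't apply.
Genomic control deflates pooled statistics when λ = median(χ²)/0.455
exceeds 1; the genome-wide threshold 5×10⁻⁸ is divided by the 2.2 effective
tests implied by running three correlated models (→ 2.27×10⁻⁸); a hit
replicates when the replication p < 0.05 with a concordant effect sign.

**eQTL pattern comparison.**  Each variant gets a signed score
sign(effect)·(−log₁₀ p); the GWAS and eQTL score vectors inside a locus
window are allele-harmonized and compared with Kendall's τ-b.  A
consistently negative τ across tissues says the trait-increasing alleles
lower the gene's expression.

**Synthetic cohorts.**  `nagwas.simulate` generates nuclear-family cohorts
(Hardy–Weinberg founders, Mendelian gene dropping), degrades hard calls to
imputation-like genotype probabilities at a target INFO, builds an integer
cups-per-day trait carrying recessive/dominant/additive causal effects plus
a pedigree-structured polygenic term, and fabricates eQTL patterns that do
or do not share a GWAS locus's causal structure — so the whole pipeline is
testable without any private cohort data.

## Worked example

`examples/03_meta_replication.py` runs the two-stage arithmetic on the
bundled PDSS2-locus summary statistics (28 recessive-model variants with
discovery and replication columns) and then end-to-end on synthetic cohorts
sized like the study (~370 + ~843 discovery, ~1731 replication):

```
genome-wide threshold for 2.2 effective model tests: 2.27e-08
replicated: 5 of 28 (rs2216084, rs6942255, rs7745311, rs7754744, rs9386630)
  rs2216084: discovery p 9.25e-09 -> pooled p 1.85e-09
  rs6942255: discovery p 9.79e-09 -> pooled p 1.85e-09
  rs7745311: discovery p 1.23e-08 -> pooled p 2.52e-09
  rs7754744: discovery p 8.8e-09 -> pooled p 1.85e-09
  rs9386630: discovery p 1.07e-08 -> pooled p 1.85e-09

synthetic run: discovery lambda 0.982; causal variant beta 0.0550, p 9.06e-04
replicated in third cohort: True; all-cohort pooled p 3.22e-14 (improves on discovery: True)
```

Exactly 5 of the 28 locus variants replicate (p < 0.05, concordant
direction), and pooling each with its replication estimate always improves
on the discovery p — the signature of a real, if attenuated, effect.  In
the synthetic run the discovery cohorts alone place the planted recessive
variant (true effect 0.086 on the log scale) at p ≈ 10⁻⁴; adding the
replication cohort drives the pooled p far below the 2.27×10⁻⁸ threshold.

The other examples cover cohort simulation (`01`), the three-model scan and
its power contrast (`02`), and the per-tissue τ table (`04`).  A thin CLI
(`nagwas simulate|prep|assoc|meta|eqtl-compare`) wraps the same calls for
shell pipelines.

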