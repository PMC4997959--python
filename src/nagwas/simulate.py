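"""Synthetic family cohorts for end-to-end testing of the scan pipeline.

The generator emulates the study conditions of a two-stage family-based
GWAS of coffee consumption: nuclear-family cohorts (parents plus siblings),
hard-call founder genotypes in Hardy-Weinberg proportions propagated by
Mendelian gene dropping, an optional degradation to imputation-like dosages
with a controllable INFO score, and an integer cups-per-day phenotype whose
log10(cups+1) transform carries the causal effects:

    latent = intercept + sum_j beta_j * code_j(G) + polygenic + sex/age + e
    cups   = round(10^latent - 1), clipped at 0.

The polygenic term is drawn per family from the pedigree-expected kinship
(variance sigma2_g = h2/(1-h2) * sigma_e^2, so h2 is the narrow-sense
heritability of the latent residual trait).  Matched cis-eQTL patterns that
share (or do not share) the causal structure of a GWAS locus can be
generated for the signed-score comparison machinery.

All generators are deterministic given (config, seed): each stage draws
from its own seed stream derived from ``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    AssocResult,
    EqtlRecord,
    GenotypeMatrix,
    KinshipMatrix,
    ValidationError,
    Variant,
)

# stage tags for per-stage RNG streams
_S_PED, _S_GENO, _S_IMPUTE, _S_PHENO, _S_EQTL = 11, 23, 37, 53, 71


@dataclass(frozen=True)
class Individual:
    id: str
    father: Optional[str]
    mother: Optional[str]
    sex: int  # 0 female, 1 male

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    individuals: List[Individual]

    def __post_init__(self) -> None:
        seen = set()
        for ind in self.individuals:
            if (ind.father is None) != (ind.mother is None):
                raise ValidationError(f"{ind.id}: needs two parents or none")
            for par in (ind.father, ind.mother):
                if par is not None and par not in seen:
                    raise ValidationError(
                        f"{ind.id}: parent {par} missing or listed later"
                    )
            if ind.id in seen:
                raise ValidationError(f"duplicate individual {ind.id}")
            seen.add(ind.id)

    @property
    def ids(self) -> List[str]:
        return [i.id for i in self.individuals]

    @property
    def n(self) -> int:
        return len(self.individuals)

    def founders(self) -> List[Individual]:
        return [i for i in self.individuals if i.is_founder]

    def trios(self) -> List[Tuple[str, str, str]]:
        return [(i.id, i.father, i.mother) for i in self.individuals
                if not i.is_founder]


@dataclass(frozen=True)
class CausalSpec:
    """A causal variant: effect ``beta`` on the log10(cups+1) scale under the
    given genetic model, at coded-allele frequency ``freq``.

    ``freq`` is the frequency of the coded (effect) allele and may exceed
    0.5 — e.g. a recessive effect with coded-homozygote frequency 0.3 needs
    a coded-allele frequency of about 0.55.
    """

    variant_id: str
    model: str = "recessive"
    beta: float = 0.086
    freq: float = 0.548

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValidationError("beta must be finite")
        if not 0 < self.freq < 1:
            raise ValidationError("freq must lie in (0, 1)")
        if self.model not in ("additive", "dominant", "recessive"):
            raise ValidationError(f"unknown model {self.model!r}")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generation parameters.

    Defaults are chosen to mimic a small isolated-population cohort: a few
    hundred nuclear families of 2-3 siblings, common variants, a latent
    trait with mean cups/day around 2 and heritability ~0.4 (within the
    0.36-0.58 range reported for coffee-consumption twin studies).
    """

    n_families: int = 100
    sibs_min: int = 2
    sibs_max: int = 3
    n_variants: int = 500
    maf_low: float = 0.05
    maf_high: float = 0.5
    target_info: float = 1.0
    h2_polygenic: float = 0.4
    sigma_e: float = 0.19
    intercept: float = 0.5
    sex_effect: float = -0.03
    age_effect: float = 0.0015
    age_low: float = 18.0
    age_high: float = 80.0
    med_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_families, self.sibs_min, self.n_variants) < 1:
            raise ValidationError("counts must be >= 1")
        if self.sibs_max < self.sibs_min:
            raise ValidationError("sibs_max < sibs_min")
        if not 0 <= self.h2_polygenic < 1:
            raise ValidationError("h2_polygenic must lie in [0, 1)")
        if not self.sigma_e > 0:
            raise ValidationError("sigma_e must be > 0")
        if not 0 < self.target_info <= 1:
            raise ValidationError("target_info must lie in (0, 1]")

    @property
    def sigma2_g(self) -> float:
        """Polygenic variance implied by h2 and sigma_e on the latent scale."""
        h2 = self.h2_polygenic
        return h2 / (1.0 - h2) * self.sigma_e**2


def _rng(config: SimConfig, stage: int, seed: Optional[int] = None):
    return np.random.default_rng(
        (config.seed if seed is None else seed, stage))


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Nuclear families: two unrelated founders plus 2-3 (configurable) sibs."""
    rng = _rng(config, _S_PED)
    inds: List[Individual] = []
    for f in range(config.n_families):
        fa, mo = f"F{f}_p1", f"F{f}_p2"
        inds.append(Individual(fa, None, None, 1))
        inds.append(Individual(mo, None, None, 0))
        n_sibs = int(rng.integers(config.sibs_min, config.sibs_max + 1))
        for k in range(n_sibs):
            sex = int(rng.integers(0, 2))
            inds.append(Individual(f"F{f}_c{k}", fa, mo, sex))
    return Pedigree(inds)


def pedigree_kinship(pedigree: Pedigree) -> KinshipMatrix:
    """Expected (pedigree-based) kinship by the tabular method."""
    ids = pedigree.ids
    pos = {s: i for i, s in enumerate(ids)}
    n = pedigree.n
    K = np.zeros((n, n))
    for i, ind in enumerate(pedigree.individuals):
        if ind.is_founder:
            K[i, i] = 0.5
        else:
            f, m = pos[ind.father], pos[ind.mother]
            K[i, i] = 0.5 + 0.5 * K[f, m]
            for j in range(i):
                K[i, j] = K[j, i] = 0.5 * (K[f, j] + K[m, j])
    return KinshipMatrix(ids, K)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    pedigree: Pedigree,
    config: SimConfig,
    freq_overrides: Optional[Dict[str, float]] = None,
    store_gp: bool = True,
) -> GenotypeMatrix:
    """Hard-call genotypes: Hardy-Weinberg founders, Mendelian gene dropping.

    Variants are unlinked (no LD beyond family co-inheritance) and named
    v000001..; ``freq_overrides`` pins the allele1 frequency of named
    variants (e.g. a causal variant).
    """
    rng = _rng(config, _S_GENO)
    m = config.n_variants
    freqs = rng.uniform(config.maf_low, config.maf_high, size=m)
    variants = [Variant(f"v{j + 1:06d}", "1", 1000 * (j + 1), "A", "G")
                for j in range(m)]
    if freq_overrides:
        idx = {v.id: j for j, v in enumerate(variants)}
        for vid, fr in freq_overrides.items():
            if vid not in idx:
                raise ValidationError(f"freq override for unknown variant {vid}")
            freqs[idx[vid]] = fr

    n = pedigree.n
    pos = {s: i for i, s in enumerate(pedigree.ids)}
    H = np.zeros((2, n, m), dtype=np.int8)
    for ind in pedigree.individuals:
        i = pos[ind.id]
        if ind.is_founder:
            H[0, i] = rng.random(m) < freqs
            H[1, i] = rng.random(m) < freqs
        else:
            f, mo = pos[ind.father], pos[ind.mother]
            pick_f = rng.integers(0, 2, size=m)
            pick_m = rng.integers(0, 2, size=m)
            H[0, i] = np.where(pick_f == 0, H[0, f], H[1, f])
            H[1, i] = np.where(pick_m == 0, H[0, mo], H[1, mo])
    dosage = (H[0] + H[1]).astype(float)

    gp = None
    if store_gp:
        gp = np.zeros((n, m, 3))
        for g in (0, 1, 2):
            gp[:, :, g] = dosage == g
    return GenotypeMatrix(variants, pedigree.ids, dosage, gp=gp,
                          info=realized_info(dosage))


def realized_info(dosage: np.ndarray) -> np.ndarray:
    """Imputation-quality INFO per variant: var(dosage) / (2 p (1-p)),
    with p the empirical coded-allele frequency, clipped to [0, 1]."""
    p = dosage.mean(axis=0) / 2.0
    het = 2.0 * p * (1.0 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        info = np.where(het > 0, dosage.var(axis=0) / het, 1.0)
    return np.clip(info, 0.0, 1.0)


def degrade_to_imputed(
    genotypes: GenotypeMatrix, target_info: float, seed: int = 0
) -> GenotypeMatrix:
    """Blend hard-call genotype certainty with the Hardy-Weinberg background
    so the realized INFO score matches ``target_info``.

    Per variant, each one-hot GP triplet becomes
    (1-a) * onehot + a * (q^2, 2pq, p^2) with the blend weight solved from
    the empirical hard-call dosage variance, which leaves the allele
    frequency unchanged and scales the dosage variance by (1-a)^2.
    ``target_info = 1`` returns the input unchanged.  ``seed`` is accepted
    for interface uniformity; the blend itself is deterministic.
    """
    if not 0 < target_info <= 1:
        raise ValidationError("target_info must lie in (0, 1]")
    if target_info == 1.0:
        return genotypes
    d = genotypes.dosage
    if not np.all(np.abs(d - np.round(d)) < 1e-9):
        raise ValidationError("degrade_to_imputed expects hard-call input")
    n, m = d.shape
    onehot = np.zeros((n, m, 3))
    for g in (0, 1, 2):
        onehot[:, :, g] = np.round(d) == g
    p = d.mean(axis=0) / 2.0
    het = 2.0 * p * (1.0 - p)
    var_hard = d.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = 1.0 - np.sqrt(np.where(var_hard > 0,
                                   target_info * het / var_hard, 1.0))
    a = np.clip(a, 0.0, 1.0)
    hw = np.stack([(1 - p) ** 2, het, p**2], axis=1)  # m x 3
    gp = (1.0 - a)[None, :, None] * onehot + a[None, :, None] * hw[None, :, :]
    dosage = gp[:, :, 1] + 2.0 * gp[:, :, 2]
    return GenotypeMatrix(list(genotypes.variants), list(genotypes.samples),
                          dosage, gp=gp, info=realized_info(dosage))


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------

def simulate_phenotype(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    causal: Sequence[CausalSpec],
    config: SimConfig,
) -> Tuple[pd.DataFrame, Dict]:
    """Integer cups-per-day phenotype carrying the causal effects.

    Returns the phenotype table (sample, cups_per_day, sex, age,
    hypertensive_med) and a truth record (causal specs, latent values,
    variance components) for parameter-recovery tests.  Medication status is
    assigned independently of genotype.
    """
    from .coding import code_genotype  # local import: no cycle at module load

    rng = _rng(config, _S_PHENO)
    n = pedigree.n
    if genotypes.samples != pedigree.ids:
        raise ValidationError("genotype samples must match pedigree order")

    latent = np.full(n, config.intercept)
    for spec in causal:
        coded = code_genotype(genotypes, spec.variant_id, spec.model)
        latent += spec.beta * coded.values

    sigma_g = np.sqrt(config.sigma2_g)
    poly = np.zeros(n)
    if sigma_g > 0:
        Kped = pedigree_kinship(pedigree)
        # families are independent blocks; draw each from its own Cholesky
        fam_of = [i.id.split("_")[0] for i in pedigree.individuals]
        idx_by_fam: Dict[str, List[int]] = {}
        for i, f in enumerate(fam_of):
            idx_by_fam.setdefault(f, []).append(i)
        for idx in idx_by_fam.values():
            block = 2.0 * Kped.K[np.ix_(idx, idx)]
            L = np.linalg.cholesky(block + 1e-10 * np.eye(len(idx)))
            poly[idx] = sigma_g * (L @ rng.standard_normal(len(idx)))
    latent += poly

    sex = np.array([i.sex for i in pedigree.individuals], dtype=float)
    age = rng.uniform(config.age_low, config.age_high, size=n)
    age_mid = 0.5 * (config.age_low + config.age_high)
    latent += config.sex_effect * sex + config.age_effect * (age - age_mid)
    latent += config.sigma_e * rng.standard_normal(n)

    cups = np.clip(np.round(10.0**latent - 1.0), 0, None).astype(int)
    med = rng.random(n) < config.med_fraction
    table = pd.DataFrame({
        "sample": pedigree.ids,
        "cups_per_day": cups,
        "sex": sex.astype(int),
        "age": age,
        "hypertensive_med": med,
    })
    truth = {
        "causal": list(causal),
        "h2_polygenic": config.h2_polygenic,
        "sigma2_g": config.sigma2_g,
        "sigma2_e": config.sigma_e**2,
        "latent": latent,
        "seed": config.seed,
    }
    return table, truth


# ---------------------------------------------------------------------------
# matched eQTL patterns
# ---------------------------------------------------------------------------

def simulate_eqtl_pattern(
    gwas_results: Sequence[AssocResult],
    shared_fraction: float,
    sign_correlation: str = "negative",
    noise_sd: float = 0.3,
    seed: int = 0,
    gene: str = "GENE1",
    tissue: str = "",
) -> List[EqtlRecord]:
    """cis-eQTL records whose signed scores track a GWAS pattern.

    For the shared fraction of variants the eQTL signed score is
    sign * (gwas_score + N(0, noise_sd)); the remainder is null (p uniform,
    slope sign random).  ``sign_correlation`` 'negative' plants an
    anti-concordant pattern (higher trait association <-> lower expression).
    """
    if not gwas_results:
        raise ValidationError("gwas_results must be non-empty")
    if not 0 <= shared_fraction <= 1:
        raise ValidationError("shared_fraction must lie in [0, 1]")
    if sign_correlation not in ("negative", "positive"):
        raise ValidationError("sign_correlation must be negative or positive")
    from .eqtl import signed_score

    rng = np.random.default_rng((seed, _S_EQTL))
    sgn = -1.0 if sign_correlation == "negative" else 1.0
    n = len(gwas_results)
    n_shared = int(round(shared_fraction * n))
    shared = np.zeros(n, dtype=bool)
    shared[rng.choice(n, size=n_shared, replace=False)] = True

    out: List[EqtlRecord] = []
    for i, r in enumerate(gwas_results):
        if shared[i]:
            s = sgn * (signed_score(r.beta, r.p)
                       + (noise_sd * rng.standard_normal() if noise_sd > 0
                          else 0.0))
            p = float(10.0 ** (-min(abs(s), 300.0)))
            slope = float(np.sign(s) if s != 0 else 1.0) * 0.1 * (abs(s) + 0.1)
        else:
            p = float(rng.uniform(np.nextafter(0, 1), 1.0))
            slope = float(rng.choice([-1.0, 1.0]) * 0.1
                          * (abs(rng.standard_normal()) + 0.05))
        out.append(EqtlRecord(r.variant, gene, slope, p, tissue=tissue))
    return out


# ---------------------------------------------------------------------------
# convenience: a whole cohort in one call
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    name: str
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: Dict = field(default_factory=dict)


def simulate_cohort(
    config: SimConfig,
    causal: Sequence[CausalSpec] = (),
    name: str = "cohort",
    store_gp: bool = True,
) -> Cohort:
    """Pedigree + genotypes (+ optional imputation degradation) + phenotype."""
    ped = simulate_pedigree(config)
    overrides = {c.variant_id: c.freq for c in causal}
    gm = simulate_genotypes(ped, config, freq_overrides=overrides,
                            store_gp=store_gp or config.target_info < 1)
    pheno, truth = simulate_phenotype(gm, ped, causal, config)
    if config.target_info < 1:
        gm = degrade_to_imputed(gm, config.target_info, seed=config.seed)
    return Cohort(name, ped, gm, pheno, truth)
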