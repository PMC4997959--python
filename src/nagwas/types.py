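"""Shared domain types for the association pipeline.

The containers here are deliberately thin: genotype and kinship matrices wrap
numpy arrays, phenotype tables are pandas DataFrames with a fixed column
contract, and per-variant results are frozen dataclasses.  Every container
knows how to validate its own invariants; validation raises, it never
silently repairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

GP_TOL = 1e-6

MODELS = ("additive", "dominant", "recessive")

#: Required columns of a phenotype table (pandas DataFrame).
PHENOTYPE_COLUMNS = ("sample", "cups_per_day", "sex", "age", "hypertensive_med")


class ValidationError(ValueError):
    """An input violated a container invariant."""


@dataclass(frozen=True)
class Variant:
    """A biallelic variant; ``allele1`` is always the coded/effect allele."""

    id: str
    chrom: str
    pos: int
    allele0: str
    allele1: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("variant id must be non-empty")
        if self.pos < 1:
            raise ValidationError(f"{self.id}: pos must be >= 1 (1-based)")
        if self.allele0 == self.allele1:
            raise ValidationError(f"{self.id}: allele0 == allele1 ({self.allele0})")

    @property
    def allele_set(self) -> frozenset:
        return frozenset((self.allele0, self.allele1))

    def is_palindromic(self) -> bool:
        """True for strand-ambiguous (A/T or C/G) SNPs."""
        return self.allele_set in (frozenset("AT"), frozenset("CG"))


@dataclass
class GenotypeMatrix:
    """Dosages (and optionally genotype probabilities) for n samples x m variants.

    ``dosage[i, j]`` is the expected count of ``variants[j].allele1`` carried by
    ``samples[i]``, in [0, 2].  When genotype probabilities are present,
    ``gp[i, j]`` is (P(hom-allele0), P(het), P(hom-allele1)) and must be
    consistent with the dosage.  ``info`` is the per-variant imputation
    quality in [0, 1].
    """

    variants: list
    samples: list
    dosage: np.ndarray
    gp: Optional[np.ndarray] = None
    info: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        if self.info is None:
            self.info = np.ones(len(self.variants))
        self.info = np.asarray(self.info, dtype=float)
        if self.gp is not None:
            self.gp = np.asarray(self.gp, dtype=float)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        for j, v in enumerate(self.variants):
            if v.id == variant_id:
                return j
        raise KeyError(f"variant {variant_id!r} not in genotype matrix")

    def coded_allele_freq(self) -> np.ndarray:
        """Empirical frequency of allele1 per variant (mean dosage / 2)."""
        return self.dosage.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.coded_allele_freq()
        return np.minimum(p, 1.0 - p)

    def validate(self) -> None:
        if np.any(self.dosage < -GP_TOL) or np.any(self.dosage > 2 + GP_TOL):
            bad = np.argwhere((self.dosage < -GP_TOL) | (self.dosage > 2 + GP_TOL))[0]
            raise ValidationError(
                f"dosage outside [0,2] at sample {self.samples[bad[0]]}, "
                f"variant {self.variants[bad[1]].id}"
            )
        if self.info.shape != (self.n_variants,):
            raise ValidationError("info must be one value per variant")
        if np.any(self.info < -GP_TOL) or np.any(self.info > 1 + GP_TOL):
            raise ValidationError("info scores must lie in [0,1]")
        if self.gp is not None:
            if self.gp.shape != (self.n_samples, self.n_variants, 3):
                raise ValidationError(f"gp shape {self.gp.shape} invalid")
            if np.any(self.gp < -GP_TOL):
                raise ValidationError("genotype probabilities must be >= 0")
            sums = self.gp.sum(axis=2)
            if np.any(np.abs(sums - 1.0) > GP_TOL):
                i, j = np.argwhere(np.abs(sums - 1.0) > GP_TOL)[0]
                raise ValidationError(
                    f"gp triplet does not sum to 1 at sample {self.samples[i]}, "
                    f"variant {self.variants[j].id} (sum={sums[i, j]:.8f})"
                )
            implied = self.gp[:, :, 1] + 2.0 * self.gp[:, :, 2]
            if np.any(np.abs(implied - self.dosage) > GP_TOL):
                i, j = np.argwhere(np.abs(implied - self.dosage) > GP_TOL)[0]
                raise ValidationError(
                    f"dosage inconsistent with gp at sample {self.samples[i]}, "
                    f"variant {self.variants[j].id}"
                )

    def subset_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            variants=list(self.variants),
            samples=[self.samples[i] for i in idx],
            dosage=self.dosage[idx],
            gp=None if self.gp is None else self.gp[idx],
            info=self.info.copy(),
        )


def validate_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Check the phenotype-table column contract and value invariants."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns: {missing}")
    if (table["cups_per_day"] < 0).any():
        raise ValidationError("cups_per_day must be non-negative")
    if not table["sex"].isin([0, 1]).all():
        raise ValidationError("sex must be coded 0/1")
    if "y_transformed" in table.columns and table["y_transformed"].notna().all():
        expected = np.log10(table["cups_per_day"].to_numpy(dtype=float) + 1.0)
        if np.any(np.abs(table["y_transformed"].to_numpy(dtype=float) - expected) > 1e-12):
            raise ValidationError("y_transformed != log10(cups_per_day + 1)")
    return table


@dataclass(frozen=True)
class AssocResult:
    """Per-variant, per-model association result on the transformed trait."""

    variant: Variant
    model: str
    beta: float
    se: float
    p: float
    n: int
    coded_freq: float
    cohort: str = ""
    info: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValidationError(f"unknown model {self.model!r}")
        if not self.se > 0:
            raise ValidationError(f"{self.variant.id}: se must be > 0")
        if not (0 < self.p <= 1):
            raise ValidationError(f"{self.variant.id}: p must lie in (0,1]")

    @property
    def chi2(self) -> float:
        return (self.beta / self.se) ** 2


@dataclass(frozen=True)
class EqtlRecord:
    """A cis-eQTL summary record: effect of allele1 on gene expression."""

    variant: Variant
    gene: str
    slope: float
    p: float
    tissue: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValidationError(f"{self.variant.id}: p must lie in (0,1]")


@dataclass(frozen=True)
class MetaResult:
    """Inverse-variance pooled result across cohorts for one variant/model."""

    variant: Variant
    model: str
    per_cohort: tuple
    beta_pooled: float
    se_pooled: float
    p_pooled: float
    lambda_applied: float = 1.0
    replicated: Optional[bool] = None
    direction_concordant: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.se_pooled > 0:
            raise ValidationError("se_pooled must be > 0")
        # pooled variance never exceeds the smallest input variance; after
        # genomic control the pooled se is inflated by sqrt(lambda)
        ses = [se for (_, _, se, _) in self.per_cohort]
        lam = max(self.lambda_applied, 1.0)
        if ses and self.se_pooled > min(ses) * np.sqrt(lam) + 1e-12:
            raise ValidationError("pooled se exceeds the smallest per-cohort se")

    def with_flags(self, **kw) -> "MetaResult":
        return replace(self, **kw)


@dataclass
class KinshipMatrix:
    """Pairwise kinship coefficients; the mixed model uses 2K as covariance."""

    samples: list
    K: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.samples)
        if self.K.shape != (n, n):
            raise ValidationError(f"kinship shape {self.K.shape} != ({n}, {n})")
        if np.max(np.abs(self.K - self.K.T)) > 1e-10:
            raise ValidationError("kinship matrix not symmetric")

    def validate_psd(self, tol: float = 1e-8) -> None:
        w = np.linalg.eigvalsh(2.0 * self.K)
        if w.min() < -tol:
            raise ValidationError(
                f"2K is not positive semi-definite (min eigenvalue {w.min():.3e}); "
                "consider adding a small ridge to the diagonal"
            )


@dataclass
class PolygenicFit:
    """Null polygenic mixed-model fit, reused for every variant's score test.

    Covariance model: y = X beta + g + e with g ~ N(0, 2K sigma2_g) and
    e ~ N(0, I sigma2_e).  The eigendecomposition of 2K is cached so V^{-1}
    products cost one rotation.
    """

    samples: list
    sigma2_g: float
    sigma2_e: float
    fixed_effects: np.ndarray
    residuals: np.ndarray          # y - X beta_gls (orthogonal to X under V^-1)
    loglik: float
    eigvecs: np.ndarray            # U from 2K = U diag(d) U'
    eigvals: np.ndarray
    X: np.ndarray
    identifiable: bool = True

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return 0.0 if tot == 0 else self.sigma2_g / tot

    @property
    def n(self) -> int:
        return len(self.samples)

    def v_weights(self) -> np.ndarray:
        """Eigenvalues of V = 2K sigma2_g + I sigma2_e in the cached basis."""
        return self.sigma2_g * self.eigvals + self.sigma2_e

    def vinv_dot(self, a: np.ndarray) -> np.ndarray:
        """V^{-1} a via the cached eigendecomposition."""
        at = self.eigvecs.T @ a
        if at.ndim == 1:
            return self.eigvecs @ (at / self.v_weights())
        return self.eigvecs @ (at / self.v_weights()[:, None])
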