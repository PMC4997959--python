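"""Genetic-model genotype coding, variant QC, and the per-variant scan.

Additive coding is the allele1 dosage (0..2).  The non-additive codings use
the imputation genotype probabilities when available: the recessive code is
P(hom-allele1), the dominant code is P(het) + P(hom-allele1).  On hard calls
these reduce to the usual 0/1 indicators.  Coding is always with respect to
allele1; testing the other allele is an explicit recode, never implicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .mixedmodel import PolygenicFit, fit_polygenic, score_test_batch
from .phenotype import build_design
from .types import (
    AssocResult,
    GenotypeMatrix,
    KinshipMatrix,
    ValidationError,
)

log = logging.getLogger(__name__)

MAX_CODE = {"additive": 2.0, "dominant": 1.0, "recessive": 1.0}


@dataclass(frozen=True)
class ModelCodedVector:
    model: str
    values: np.ndarray
    coded_freq: float

    def __post_init__(self) -> None:
        hi = MAX_CODE[self.model]
        v = np.asarray(self.values, dtype=float)
        if np.any(v < -1e-9) or np.any(v > hi + 1e-9):
            raise ValidationError(f"{self.model} codes must lie in [0, {hi:g}]")
        if abs(self.coded_freq - v.mean() / hi) > 1e-9:
            raise ValidationError("coded_freq inconsistent with values")


def _is_hardcall(values: np.ndarray) -> bool:
    return bool(np.all(np.abs(values - np.round(values)) < 1e-9))


def _code_columns(
    gm: GenotypeMatrix, j: slice, model: str, recessive_coding: str = "gp"
) -> np.ndarray:
    """Coded values for a block of variant columns (n x k)."""
    d = gm.dosage[:, j]
    if model == "additive":
        return d
    if gm.gp is not None and recessive_coding == "gp":
        gp = gm.gp[:, j, :]
        return gp[:, :, 2] if model == "recessive" else gp[:, :, 1] + gp[:, :, 2]
    if gm.gp is not None and recessive_coding == "hardcall":
        best = np.argmax(gm.gp[:, j, :], axis=2).astype(float)
        return (best == 2).astype(float) if model == "recessive" \
            else (best >= 1).astype(float)
    if not _is_hardcall(d):
        raise ValidationError(
            f"{model} coding on fractional dosages requires genotype "
            "probabilities (GP) or hard calls"
        )
    r = np.round(d)
    return (r == 2).astype(float) if model == "recessive" else (r >= 1).astype(float)


def code_genotype(
    gm: GenotypeMatrix, variant_id: str, model: str,
    recessive_coding: str = "gp",
) -> ModelCodedVector:
    """Code one variant under a genetic model; allele1 is the coded allele."""
    if model not in MAX_CODE:
        raise ValidationError(f"unknown model {model!r}")
    j = gm.variant_index(variant_id)
    vals = _code_columns(gm, slice(j, j + 1), model, recessive_coding)[:, 0]
    return ModelCodedVector(model, vals, float(vals.mean() / MAX_CODE[model]))


def variant_qc(
    gm: GenotypeMatrix, maf_min: float = 0.01, info_min: float = 0.4
) -> Tuple[np.ndarray, Dict[str, int]]:
    """Post-imputation variant filter: fail when MAF or info falls below the
    cutoff (strict inequality, so a variant at exactly the cutoff passes).

    ``info_min`` doubles as the R^2 cutoff for cohorts whose imputation
    quality field holds R^2 (e.g. 0.3 instead of 0.4); which threshold
    applies is per-cohort configuration.
    """
    maf = gm.maf()
    fail_maf = maf < maf_min
    fail_info = gm.info < info_min
    keep = ~(fail_maf | fail_info)
    report = {
        "n_variants": gm.n_variants,
        "fail_maf": int(fail_maf.sum()),
        "fail_info": int(fail_info.sum()),
        "n_pass": int(keep.sum()),
    }
    return keep, report


def coded_category_filter(
    coded: ModelCodedVector, low: float = 0.01, high: float = 0.99
) -> bool:
    """True iff the coded-category frequency lies in [low, high].

    Rare coded categories (e.g. a handful of coded homozygotes under the
    recessive model) destabilize the test and are removed; the comparison is
    strict, so a frequency of exactly ``low`` passes.
    """
    return not (coded.coded_freq < low or coded.coded_freq > high)


@dataclass(frozen=True)
class ScanConfig:
    models: Tuple[str, ...] = ("additive", "dominant", "recessive")
    maf_min: float = 0.01
    info_min: float = 0.4
    coded_low: float = 0.01
    coded_high: float = 0.99
    recessive_coding: str = "gp"
    cohort: str = ""


def run_scan(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    kinship: KinshipMatrix,
    config: ScanConfig = ScanConfig(),
    fit: PolygenicFit | None = None,
) -> List[AssocResult]:
    """Per-variant association scan under each requested genetic model.

    Samples are aligned on the phenotype table (which must already carry
    ``y_transformed``); the polygenic null model is fitted once and reused
    for every variant.  Variants failing QC or the coded-category filter are
    skipped; untestable variants (no coded variance after covariate
    adjustment) are logged and skipped.
    """
    samples = phenotypes["sample"].tolist()
    gidx = {s: i for i, s in enumerate(genotypes.samples)}
    missing = [s for s in samples if s not in gidx]
    if missing:
        raise ValidationError(f"samples missing from genotypes: {missing[:5]}")
    gm = genotypes.subset_samples([gidx[s] for s in samples])

    if fit is None:
        kidx = {s: i for i, s in enumerate(kinship.samples)}
        order = [kidx[s] for s in samples]
        K = KinshipMatrix(samples, kinship.K[np.ix_(order, order)])
        y, X = build_design(phenotypes)
        fit = fit_polygenic(y, X, K)

    keep, _ = variant_qc(gm, config.maf_min, config.info_min)
    n = gm.n_samples
    results: List[AssocResult] = []
    for model in config.models:
        cols = np.flatnonzero(keep)
        try:
            coded = _code_columns(gm, cols, model, config.recessive_coding)
        except ValidationError as exc:
            log.warning("model %s skipped: %s", model, exc)
            continue
        freqs = coded.mean(axis=0) / MAX_CODE[model]
        ok = (freqs >= config.coded_low) & (freqs <= config.coded_high)
        test_cols = cols[ok]
        if test_cols.size == 0:
            continue
        stats_ = score_test_batch(coded[:, ok], fit)
        for j, st, cf in zip(test_cols, stats_, freqs[ok]):
            if not st.testable:
                log.warning("variant %s (%s): untestable, skipped",
                            gm.variants[j].id, model)
                continue
            results.append(AssocResult(
                variant=gm.variants[j], model=model, beta=st.beta, se=st.se,
                p=st.p, n=n, coded_freq=float(cf), cohort=config.cohort,
                info=float(gm.info[j]),
            ))
    return results
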