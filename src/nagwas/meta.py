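"""Inverse-variance meta-analysis, genomic control, and replication logic.

Standard GWAS meta-analysis tools assume additive effects; the pooling here
is deliberately model-agnostic — the fixed-effect inverse-variance arithmetic
is identical whichever genetic model produced the per-cohort estimates, so
dominant and recessive scans pool exactly like additive ones.

Order of operations for a two-stage design: per-cohort scans are pooled
across the discovery cohorts, genomic control is applied to the pooled
statistics, survivors of the significance threshold go to replication, and
finally all cohorts (discovery + replication) are pooled together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .eqtl import harmonize_alleles
from .types import AssocResult, MetaResult, ValidationError

log = logging.getLogger(__name__)

#: Median of the chi-square(1) distribution, the null reference for lambda.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


def _two_sided_p(z: float) -> float:
    return float(min(1.0, max(2.0 * stats.norm.sf(abs(z)), 5e-324)))


@dataclass(frozen=True)
class ThresholdSpec:
    """Genome-wide threshold corrected for the effective number of genetic
    models tested per variant (three correlated codings count as ~2.2
    independent tests)."""

    alpha_gw: float = 5e-8
    n_eff_models: float = 2.2

    def __post_init__(self) -> None:
        if self.alpha_gw <= 0 or self.n_eff_models <= 0:
            raise ValidationError("alpha_gw and n_eff_models must be positive")

    @property
    def threshold(self) -> float:
        return self.alpha_gw / self.n_eff_models


def significance_threshold(
    alpha_gw: float = 5e-8, n_eff_models: float = 2.2
) -> ThresholdSpec:
    return ThresholdSpec(alpha_gw, n_eff_models)


def inverse_variance_meta(
    inputs: Sequence[Tuple[float, float]]
) -> Tuple[float, float, float]:
    """Fixed-effect pooling of (beta, se) pairs.

    Weights are 1/se^2; returns (beta_pooled, se_pooled, p_pooled) with a
    two-sided normal p-value.
    """
    if len(inputs) == 0:
        raise ValidationError("need at least one (beta, se) input")
    betas = np.array([b for b, _ in inputs], dtype=float)
    ses = np.array([s for _, s in inputs], dtype=float)
    if np.any(ses <= 0):
        raise ValidationError("all standard errors must be > 0")
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    return beta, se, _two_sided_p(beta / se)


def meta_analyze(
    cohort_results: Mapping[str, Sequence[AssocResult]]
) -> List[MetaResult]:
    """Pool per-cohort scans by variant and model.

    Effect alleles are harmonized to the orientation of the first cohort in
    which a variant appears (a swapped effect allele flips the sign).
    Variants present in only a subset of cohorts are pooled over that subset.
    """
    if not cohort_results:
        raise ValidationError("no cohorts to pool")
    order: List[Tuple[str, str]] = []
    bucket: Dict[Tuple[str, str], List[Tuple[str, AssocResult]]] = {}
    for cohort, results in cohort_results.items():
        for r in results:
            key = (r.variant.id, r.model)
            if key not in bucket:
                bucket[key] = []
                order.append(key)
            bucket[key].append((cohort, r))
    out: List[MetaResult] = []
    for key in order:
        entries = bucket[key]
        ref = entries[0][1]
        per_cohort = []
        for cohort, r in entries:
            beta = r.beta
            if r.variant.allele_set != ref.variant.allele_set:
                log.warning("%s: allele sets incompatible in %s, dropped",
                            r.variant.id, cohort)
                continue
            if r.variant.allele1 == ref.variant.allele0:
                beta = -beta
            per_cohort.append((cohort, beta, r.se, r.p))
        bp, sp, pp = inverse_variance_meta([(b, s) for _, b, s, _ in per_cohort])
        out.append(MetaResult(ref.variant, ref.model, tuple(per_cohort),
                              bp, sp, pp))
    return out


Result = Union[AssocResult, MetaResult]


def genomic_control(results: Sequence[Result]) -> Tuple[float, List[Result]]:
    """Estimate the inflation factor lambda and, when lambda > 1, deflate.

    lambda = median((beta/se)^2) / median(chi-square_1).  Correction divides
    each chi-square by lambda, implemented as se <- se * sqrt(lambda) with p
    recomputed, so beta/se/p stay mutually consistent.  lambda <= 1 leaves
    the results untouched (lambda is still reported).
    """
    if len(results) == 0:
        raise ValidationError("genomic control needs at least one result")
    if len(results) < 100:
        log.warning("genomic control on %d results; lambda is unstable below "
                    "~100", len(results))
    is_meta = isinstance(results[0], MetaResult)
    chi2 = np.array([
        (r.beta_pooled / r.se_pooled) ** 2 if is_meta else (r.beta / r.se) ** 2
        for r in results
    ])
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    if lam <= 1.0:
        corrected = [
            r.with_flags(lambda_applied=lam) if is_meta else r for r in results
        ]
        return lam, list(corrected)
    s = float(np.sqrt(lam))
    corrected = []
    for r in results:
        if is_meta:
            se = r.se_pooled * s
            corrected.append(r.with_flags(
                se_pooled=se, p_pooled=_two_sided_p(r.beta_pooled / se),
                lambda_applied=lam,
            ))
        else:
            from dataclasses import replace
            se = r.se * s
            corrected.append(replace(r, se=se, p=_two_sided_p(r.beta / se)))
    return lam, corrected


def replication_filter(
    discovery: Sequence[MetaResult],
    replication: Sequence[AssocResult],
    alpha: float = 0.05,
) -> Tuple[List[MetaResult], Dict[str, int]]:
    """Annotate discovery hits with the replication verdict.

    A hit replicates when the replication p is strictly below ``alpha`` AND
    the replication effect has the same sign as the discovery effect (after
    allele harmonization).  Unmatched variants are reported, not fatal.
    """
    rep_by_key = {}
    for r in replication:
        rep_by_key.setdefault((r.variant.id, r.model), r)
    out: List[MetaResult] = []
    report = {"n_discovery": len(discovery), "matched": 0, "unmatched": 0,
              "replicated": 0}
    for d in discovery:
        r = rep_by_key.get((d.variant.id, d.model))
        if r is None:
            report["unmatched"] += 1
            log.warning("%s (%s): no replication record", d.variant.id, d.model)
            out.append(d)
            continue
        pairs, _ = harmonize_alleles([d], [r], exclude_palindromic=False)
        if not pairs:
            report["unmatched"] += 1
            out.append(d)
            continue
        rb = pairs[0][1]
        concordant = bool(np.sign(rb.beta) == np.sign(d.beta_pooled))
        replicated = bool(rb.p < alpha and concordant)
        report["matched"] += 1
        report["replicated"] += int(replicated)
        out.append(d.with_flags(replicated=replicated,
                                direction_concordant=concordant))
    return out, report


def pool_all_cohorts(
    cohort_results: Mapping[str, Sequence[AssocResult]],
    discovery: Sequence[MetaResult] = (),
) -> Tuple[List[MetaResult], Dict[Tuple[str, str], bool]]:
    """Pool every cohort (discovery + replication) into one meta-analysis.

    When the discovery-stage meta results are supplied, the returned map
    records per (variant id, model) whether the all-cohort pooled p is lower
    than the discovery p — the signature of a consistent, replicating effect.
    """
    pooled = meta_analyze(cohort_results)
    disc_p = {(d.variant.id, d.model): d.p_pooled for d in discovery}
    improved = {}
    for m in pooled:
        key = (m.variant.id, m.model)
        if key in disc_p:
            improved[key] = bool(m.p_pooled < disc_p[key])
    return pooled, improved
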