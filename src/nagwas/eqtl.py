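"""Signed-score comparison of a GWAS locus pattern with cis-eQTL patterns.

If the trait association at a locus is driven by regulation of a nearby
gene's expression, the per-variant association strengths of the GWAS and of
the gene's cis-eQTLs should track each other across the locus.  Each variant
gets a signed score, +(-log10 p) when its effect is positive and -(-log10 p)
when negative, so the score carries both strength and direction, and the two
score vectors are compared with Kendall's tau-b (rank-based: neither score
vector is anywhere near normal).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .types import AssocResult, EqtlRecord, MetaResult, ValidationError, Variant

log = logging.getLogger(__name__)

Record = Union[AssocResult, MetaResult, EqtlRecord]


@dataclass(frozen=True)
class LocusWindow:
    """1-based inclusive genomic window, e.g. the interval between the two
    recombination hotspots flanking an association signal."""

    chrom: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValidationError("window start must be <= stop")

    def contains(self, variant: Variant) -> bool:
        return (variant.chrom == self.chrom
                and self.start <= variant.pos <= self.stop)


#: The interval between the recombination hotspots flanking the PDSS2
#: coffee-consumption signal on chromosome 6.
PDSS2_WINDOW = LocusWindow("6", 107_400_000, 107_900_000)


@dataclass(frozen=True)
class SignedScoreVector:
    variant_ids: Tuple[str, ...]
    scores: np.ndarray
    source: str = ""


def _effect_of(rec: Record) -> float:
    if isinstance(rec, EqtlRecord):
        return rec.slope
    if isinstance(rec, MetaResult):
        return rec.beta_pooled
    return rec.beta


def _p_of(rec: Record) -> float:
    if isinstance(rec, MetaResult):
        return rec.p_pooled
    return rec.p


def _with_effect(rec: Record, effect: float) -> Record:
    if isinstance(rec, EqtlRecord):
        return replace(rec, slope=effect)
    if isinstance(rec, MetaResult):
        return replace(rec, beta_pooled=effect)
    return replace(rec, beta=effect)


def signed_score(beta: float, p: float) -> float:
    """sign(beta) * (-log10 p); zero effect or p = 1 scores 0."""
    if not 0 < p <= 1:
        raise ValidationError(f"p must lie in (0, 1], got {p}")
    if not math.isfinite(beta):
        raise ValidationError("effect must be finite")
    return float(np.sign(beta) * (-math.log10(p)))


def signed_score_vector(records: Sequence[Record], source: str = "") -> SignedScoreVector:
    ids = tuple(r.variant.id for r in records)
    scores = np.array([signed_score(_effect_of(r), _p_of(r)) for r in records])
    return SignedScoreVector(ids, scores, source)


def extract_window(records: Sequence[Record], window: LocusWindow) -> List[Record]:
    """Records falling inside the window (inclusive bounds), input order kept."""
    return [r for r in records if window.contains(r.variant)]


def harmonize_alleles(
    a: Sequence[Record],
    b: Sequence[Record],
    exclude_palindromic: bool = True,
) -> Tuple[List[Tuple[Record, Record]], Dict[str, int]]:
    """Match two record sets on (chrom, pos, allele set) and align effect alleles.

    When b's effect allele (allele1) is a's other allele, b's effect sign is
    flipped so both effects refer to the same allele.  Strand-ambiguous
    (A/T, C/G) pairs cannot be oriented safely and are excluded by default.
    """
    index = {(r.variant.chrom, r.variant.pos, r.variant.allele_set): r for r in b}
    pairs: List[Tuple[Record, Record]] = []
    report = {"n_a": len(a), "n_b": len(b), "matched": 0,
              "palindromic_excluded": 0, "incompatible": 0}
    for ra in a:
        key = (ra.variant.chrom, ra.variant.pos, ra.variant.allele_set)
        rb = index.get(key)
        if rb is None:
            n_pos = sum(1 for r in b if (r.variant.chrom, r.variant.pos)
                        == key[:2])
            if n_pos:
                report["incompatible"] += 1
                log.warning("alleles incompatible at %s:%s, pair dropped",
                            ra.variant.chrom, ra.variant.pos)
            continue
        if exclude_palindromic and ra.variant.is_palindromic():
            report["palindromic_excluded"] += 1
            continue
        if rb.variant.allele1 == ra.variant.allele0:
            rb = _with_effect(rb, -_effect_of(rb))
        pairs.append((ra, rb))
        report["matched"] += 1
    return pairs, report


def kendall_compare(
    s_a: SignedScoreVector, s_b: SignedScoreVector
) -> Tuple[float, float, int]:
    """Kendall tau-b between two signed-score vectors matched on variant id.

    Two-sided p from the normal approximation; for 8 or fewer untied pairs
    the exact null permutation distribution is used instead.
    """
    common = [i for i, vid in enumerate(s_a.variant_ids)
              if vid in set(s_b.variant_ids)]
    pos_b = {vid: i for i, vid in enumerate(s_b.variant_ids)}
    x = s_a.scores[common]
    y = np.array([s_b.scores[pos_b[s_a.variant_ids[i]]] for i in common])
    n = len(x)
    if n < 3:
        raise ValidationError(f"need >= 3 matched pairs, got {n}")
    no_ties = len(set(x)) == n and len(set(y)) == n
    method = "exact" if (n <= 8 and no_ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue), n


def compare_all_tissues(
    gwas: Sequence[Record],
    eqtl_by_tissue: Dict[str, Sequence[EqtlRecord]],
    window: LocusWindow = PDSS2_WINDOW,
    exclude_palindromic: bool = True,
) -> pd.DataFrame:
    """Per-tissue Kendall tau-b between the GWAS pattern and each eQTL pattern.

    Pipeline per tissue: window extraction -> allele harmonization ->
    signed scores -> tau.  Tissues that fail (too few matched pairs) are
    logged and reported with NaN.
    """
    gwas_w = extract_window(gwas, window)
    rows = []
    for tissue in eqtl_by_tissue:
        try:
            eq_w = extract_window(eqtl_by_tissue[tissue], window)
            pairs, rep = harmonize_alleles(gwas_w, eq_w, exclude_palindromic)
            sg = signed_score_vector([a for a, _ in pairs], "gwas")
            se = signed_score_vector([b for _, b in pairs], f"eqtl:{tissue}")
            tau, p, npairs = kendall_compare(sg, se)
        except ValidationError as exc:
            log.warning("tissue %s failed: %s", tissue, exc)
            tau, p, npairs = float("nan"), float("nan"), 0
        rows.append((tissue, tau, p, npairs))
    return pd.DataFrame(rows, columns=["tissue", "tau", "p", "n_pairs"])
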