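"""Readers and writers for the plain-text formats every pipeline stage touches.

Formats
-------
* Genotypes: VCF 4.x with ``DS``/``GP`` FORMAT fields (read via cyvcf2), or a
  dosage TSV (header ``sample <variant_id> ...``, one row per sample) with an
  optional ``<path>.variants.tsv`` sidecar carrying variant metadata.
* Phenotypes: TSV with columns sample, cups_per_day, sex, age, hypertensive_med.
* Summary statistics: TSV with columns SNP CHR POS A0 A1 MODEL BETA SE P N
  CODED_FREQ INFO COHORT (per-cohort results) or the pooled-meta variant.
* cis-eQTL records: TSV with columns SNP CHR POS A0 A1 GENE SLOPE P TISSUE.

Note htslib stores FORMAT floats in single precision, so VCF round-trips are
exact only to ~1e-6 relative; the TSV routes round-trip to full precision.
"""

from __future__ import annotations

import importlib.resources
import json
import os
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    AssocResult,
    EqtlRecord,
    GenotypeMatrix,
    MetaResult,
    ValidationError,
    Variant,
    validate_phenotypes,
)

_FLOAT_FMT = "%.17g"

SUMMARY_COLUMNS = [
    "SNP", "CHR", "POS", "A0", "A1", "MODEL",
    "BETA", "SE", "P", "N", "CODED_FREQ", "INFO", "COHORT",
]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str, format: str = "auto") -> GenotypeMatrix:
    """Load a genotype matrix from a VCF (DS/GP) or a dosage TSV."""
    if format == "auto":
        format = "vcf-dosage" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf-dosage":
        return _read_vcf(path)
    if format == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    variants, dosage_cols, gp_cols, info_vals = [], [], [], []
    any_gp, all_gp = False, True
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise ValidationError(
                f"{path}: record {i + 1} ({rec.ID}) is not biallelic"
            )
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(Variant(vid, str(rec.CHROM), rec.POS, rec.REF, rec.ALT[0]))
        gp = rec.format("GP")
        ds = rec.format("DS")
        if gp is not None:
            gp = np.asarray(gp, dtype=float)
            any_gp = True
            gp_cols.append(gp)
            ds_from_gp = gp[:, 1] + 2.0 * gp[:, 2]
            ds = ds_from_gp if ds is None else np.asarray(ds, dtype=float).ravel()
            if np.any(np.abs(ds - ds_from_gp) > 1e-4):
                raise ValidationError(
                    f"{path}: record {i + 1} ({vid}): DS inconsistent with GP"
                )
        else:
            all_gp = False
            if ds is None:
                raise ValidationError(
                    f"{path}: record {i + 1} ({vid}) carries neither DS nor GP"
                )
            ds = np.asarray(ds, dtype=float).ravel()
        if np.any(ds < -1e-6) or np.any(ds > 2 + 1e-6):
            raise ValidationError(
                f"{path}: record {i + 1} ({vid}): dosage outside [0,2]"
            )
        dosage_cols.append(np.clip(ds, 0.0, 2.0))
        iv = rec.INFO.get("INFO")
        info_vals.append(1.0 if iv is None else float(iv))
    if not variants:
        raise ValidationError(f"{path}: no variant records")
    dosage = np.column_stack(dosage_cols)
    gp = None
    if any_gp:
        if not all_gp:
            raise ValidationError(f"{path}: GP present for some records only")
        gp = np.stack(gp_cols, axis=1)
        gp = np.clip(gp, 0.0, None)
        gp /= gp.sum(axis=2, keepdims=True)
        dosage = gp[:, :, 1] + 2.0 * gp[:, :, 2]
    return GenotypeMatrix(variants, samples, dosage, gp=gp,
                          info=np.asarray(info_vals))


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a genotype matrix as an uncompressed VCF with DS (and GP) fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,'
                 'Description="Imputation info score">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated allele1 dosage">\n')
        if gm.gp is not None:
            fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,'
                     'Description="Genotype probabilities">\n')
        for chrom in dict.fromkeys(v.chrom for v in gm.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in gm.samples) + "\n")
        fmt = "DS" if gm.gp is None else "DS:GP"
        for j, v in enumerate(gm.variants):
            cells = []
            for i in range(gm.n_samples):
                ds = f"{gm.dosage[i, j]:.6g}"
                if gm.gp is None:
                    cells.append(ds)
                else:
                    g = gm.gp[i, j]
                    cells.append(f"{ds}:{g[0]:.6g},{g[1]:.6g},{g[2]:.6g}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.allele0}\t{v.allele1}\t.\t.\t"
                f"INFO={gm.info[j]:.6g}\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def write_genotypes(gm: GenotypeMatrix, path: str, format: str = "auto") -> None:
    if format == "auto":
        format = "vcf-dosage" if path.endswith(".vcf") else "tsv"
    if format == "vcf-dosage":
        write_vcf(gm, path)
        return
    df = pd.DataFrame(gm.dosage, columns=[v.id for v in gm.variants])
    df.insert(0, "sample", gm.samples)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    meta = pd.DataFrame(
        {
            "SNP": [v.id for v in gm.variants],
            "CHR": [v.chrom for v in gm.variants],
            "POS": [v.pos for v in gm.variants],
            "A0": [v.allele0 for v in gm.variants],
            "A1": [v.allele1 for v in gm.variants],
            "INFO": gm.info,
        }
    )
    meta.to_csv(path + ".variants.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT)


def _read_genotype_tsv(path: str) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message is informative
        raise ValidationError(f"{path}: cannot parse dosage TSV: {exc}") from exc
    if df.columns[0] != "sample":
        raise ValidationError(f"{path}: first column must be 'sample'")
    samples = df["sample"].astype(str).tolist()
    ids = list(df.columns[1:])
    dosage = df[ids].to_numpy(dtype=float)
    sidecar = path + ".variants.tsv"
    if os.path.exists(sidecar):
        meta = pd.read_csv(sidecar, sep="\t", dtype={"CHR": str},
                           float_precision="round_trip")
        lookup = {r.SNP: r for r in meta.itertuples()}
        variants = [
            Variant(vid, str(lookup[vid].CHR), int(lookup[vid].POS),
                    lookup[vid].A0, lookup[vid].A1)
            for vid in ids
        ]
        info = np.array([float(lookup[vid].INFO) for vid in ids])
    else:
        # dosage-only table: synthesize placeholder metadata
        variants = [Variant(vid, "0", j + 1, "A", "B") for j, vid in enumerate(ids)]
        info = np.ones(len(ids))
    return GenotypeMatrix(variants, samples, dosage, info=info)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    df["sample"] = df["sample"].astype(str)
    df["hypertensive_med"] = df["hypertensive_med"].astype(bool)
    return validate_phenotypes(df)


def write_phenotypes(table: pd.DataFrame, path: str) -> None:
    validate_phenotypes(table)
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def write_summary_stats(
    results: Sequence[Union[AssocResult, MetaResult]], path: str
) -> None:
    """Write association or pooled-meta results as a summary-stats TSV."""
    if not results:
        raise ValidationError("cannot write an empty result list")
    kinds = {type(r) for r in results}
    if len(kinds) > 1:
        raise ValidationError("cannot mix AssocResult and MetaResult in one file")
    rows = []
    if isinstance(results[0], AssocResult):
        for r in results:
            v = r.variant
            rows.append((v.id, v.chrom, v.pos, v.allele0, v.allele1, r.model,
                         r.beta, r.se, r.p, r.n, r.coded_freq, r.info, r.cohort))
        df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    else:
        for r in results:
            v = r.variant
            rows.append((
                v.id, v.chrom, v.pos, v.allele0, v.allele1, r.model,
                r.beta_pooled, r.se_pooled, r.p_pooled, r.lambda_applied,
                "" if r.replicated is None else int(r.replicated),
                "" if r.direction_concordant is None else int(r.direction_concordant),
                json.dumps([[c, b, s, p] for (c, b, s, p) in r.per_cohort]),
            ))
        df = pd.DataFrame(rows, columns=[
            "SNP", "CHR", "POS", "A0", "A1", "MODEL", "BETA", "SE", "P",
            "LAMBDA", "REPLICATED", "CONCORDANT", "PER_COHORT",
        ])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_summary_stats(path: str) -> List[AssocResult]:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "COHORT": str},
                     float_precision="round_trip",
                     keep_default_na=False, na_values=[""])
    out = []
    for r in df.itertuples():
        v = Variant(str(r.SNP), str(r.CHR), int(r.POS), str(r.A0), str(r.A1))
        cohort = "" if pd.isna(getattr(r, "COHORT", "")) else str(r.COHORT)
        out.append(AssocResult(v, r.MODEL, float(r.BETA), float(r.SE),
                               float(r.P), int(r.N), float(r.CODED_FREQ),
                               cohort=cohort, info=float(r.INFO)))
    return out


def read_meta_results(path: str) -> List[MetaResult]:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str},
                     float_precision="round_trip", keep_default_na=False, na_values=[""])
    out = []
    for r in df.itertuples():
        v = Variant(str(r.SNP), str(r.CHR), int(r.POS), str(r.A0), str(r.A1))
        per_cohort = tuple(
            (c, float(b), float(s), float(p))
            for c, b, s, p in json.loads(r.PER_COHORT)
        )
        rep = None if pd.isna(r.REPLICATED) else bool(int(r.REPLICATED))
        conc = None if pd.isna(r.CONCORDANT) else bool(int(r.CONCORDANT))
        out.append(MetaResult(v, r.MODEL, per_cohort, float(r.BETA),
                              float(r.SE), float(r.P), float(r.LAMBDA),
                              replicated=rep, direction_concordant=conc))
    return out


# ---------------------------------------------------------------------------
# eQTL records
# ---------------------------------------------------------------------------

def read_eqtl(path: str) -> List[EqtlRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "TISSUE": str},
                     float_precision="round_trip")
    out = []
    for r in df.itertuples():
        v = Variant(str(r.SNP), str(r.CHR), int(r.POS), str(r.A0), str(r.A1))
        tissue = getattr(r, "TISSUE", "") or ""
        out.append(EqtlRecord(v, str(r.GENE), float(r.SLOPE), float(r.P),
                              tissue=tissue))
    return out


def write_eqtl(records: Sequence[EqtlRecord], path: str) -> None:
    if not records:
        raise ValidationError("cannot write an empty eQTL list")
    rows = [
        (r.variant.id, r.variant.chrom, r.variant.pos, r.variant.allele0,
         r.variant.allele1, r.gene, r.slope, r.p, r.tissue)
        for r in records
    ]
    pd.DataFrame(rows, columns=[
        "SNP", "CHR", "POS", "A0", "A1", "GENE", "SLOPE", "P", "TISSUE",
    ]).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# bundled fixture: PDSS2-locus recessive-scan summary statistics
# ---------------------------------------------------------------------------

def load_pdss2_locus() -> pd.DataFrame:
    """Bundled discovery + replication summary statistics for the PDSS2 locus.

    28 chromosome-6 variants from a recessive-model genome-wide scan of
    habitual coffee consumption (log10(cups+1) scale): discovery
    inverse-variance meta-analysis columns (BETA, SE, P) and replication
    cohort columns (BETA_REP, SE_REP, P_REP).  Positions are stored at the
    0.1-Mb precision of the original report.
    """
    ref = importlib.resources.files("nagwas").joinpath(
        "data", "pdss2_locus_recessive.tsv")
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", dtype={"CHR": str})
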