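"""Readers and writers for the pipeline's table formats.

Canonical interchange dialect: UTF-8 tab-separated values, one header row,
``.`` or the empty string for missing values.  Variant tables can also be
read from VCF v4.2 (via cyvcf2), where the annotation evidence travels in
INFO keys ``GNOMAD_MAX_AF``, ``CLINVAR``, ``ONCOKB``, ``AM_CLASS``,
``AM_SCORE``, ``CADD_PHRED``, ``GERMLINE_DB`` (0/1), ``CONSEQUENCE`` and
``PCHANGE``, and the VAF comes from the per-sample ``AF`` field or, failing
that, from ``AD`` as alt/(ref+alt).  Multi-allelic records are decomposed to
one variant per alt allele.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .types import (
    AlphaMissense,
    AnnotatedVariant,
    ClassifiedVariant,
    ClinVar,
    Consequence,
    OncoKB,
    PairedGermlineCall,
    PatientAtmStatus,
)

__all__ = [
    "read_variant_table",
    "read_variant_tsv",
    "read_variant_vcf",
    "variants_from_frame",
    "variants_to_frame",
    "write_variant_table",
    "classified_to_frame",
    "write_classified_table",
    "read_classified_table",
    "status_to_frame",
    "write_status_table",
    "read_clinical_table",
    "write_table",
    "read_blocklist",
]

_MISSING = {"", ".", "na", "nan", "none"}

_MANDATORY_COLUMNS = ("patient_id", "chrom", "pos", "ref", "alt", "vaf",
                      "consequence")

_ENUM_FIELDS = {
    "consequence": Consequence,
    "clinvar": ClinVar,
    "oncokb": OncoKB,
    "alphamissense": AlphaMissense,
    "paired_germline_call": PairedGermlineCall,
}

_VARIANT_COLUMNS = [
    "patient_id", "chrom", "pos", "ref", "alt", "protein_change", "vaf",
    "consequence", "gnomad_max_pop_af", "clinvar", "oncokb", "alphamissense",
    "alphamissense_score", "cadd_phred", "in_germline_dataset",
    "paired_germline_call",
]


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return isinstance(value, str) and value.strip().lower() in _MISSING


def _opt_float(value, what: str, line: Optional[int] = None) -> Optional[float]:
    if _is_missing(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        where = f" (line {line})" if line is not None else ""
        raise ValueError(f"unparseable {what} {value!r}{where}") from None


def _opt_bool(value) -> bool:
    if _is_missing(value):
        return False
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes"}
    return bool(value)


def variants_from_frame(frame: pd.DataFrame) -> List[AnnotatedVariant]:
    """Build AnnotatedVariant records from a canonical-dialect DataFrame.

    Missing annotation columns are treated as absent for every record;
    unknown columns are ignored (readers keep them as opaque extras).
    """
    for col in _MANDATORY_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"variant table missing mandatory column {col!r}")
    variants = []
    for i, row in enumerate(frame.to_dict("records")):
        line = i + 2  # header is line 1
        vaf = _opt_float(row.get("vaf"), "VAF", line)
        if vaf is None:
            raise ValueError(f"missing VAF (line {line})")
        enums = {}
        for field_name, enum_cls in _ENUM_FIELDS.items():
            raw = row.get(field_name)
            if _is_missing(raw):
                if field_name == "consequence":
                    raise ValueError(f"missing consequence (line {line})")
                if field_name == "paired_germline_call":
                    enums[field_name] = PairedGermlineCall.UNKNOWN
                else:
                    enums[field_name] = enum_cls("absent")
            else:
                enums[field_name] = enum_cls(str(raw).strip().lower())
        variants.append(
            AnnotatedVariant(
                patient_id=str(row["patient_id"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                vaf=vaf,
                protein_change=(None if _is_missing(row.get("protein_change"))
                                else str(row["protein_change"])),
                gnomad_max_pop_af=_opt_float(
                    row.get("gnomad_max_pop_af"), "gnomAD AF", line
                ),
                alphamissense_score=_opt_float(
                    row.get("alphamissense_score"), "AlphaMissense score", line
                ),
                cadd_phred=_opt_float(row.get("cadd_phred"), "CADD phred", line),
                in_germline_dataset=_opt_bool(row.get("in_germline_dataset")),
                **enums,
            )
        )
    return variants


def read_variant_tsv(path: str) -> List[AnnotatedVariant]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return variants_from_frame(frame)


def read_variant_vcf(path: str) -> List[AnnotatedVariant]:
    """Read variants from a VCF, one record per (sample with the alt, alt).

    VAF comes from the per-sample ``AF`` format field when present,
    otherwise from ``AD`` as alt/(ref+alt); ``DP`` alone is never used.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples; VAF unavailable")
    out = []
    for rec in vcf:
        info = dict(rec.INFO)
        consequence_raw = info.get("CONSEQUENCE")
        if consequence_raw is None:
            raise ValueError(
                f"{path}: record {rec.CHROM}:{rec.POS} lacks the CONSEQUENCE "
                "INFO key"
            )
        af_field = rec.format("AF")
        ad_field = rec.format("AD")
        if af_field is None and ad_field is None:
            raise ValueError(
                f"{path}: record {rec.CHROM}:{rec.POS} has neither AF nor AD "
                "genotype fields"
            )
        for alt_idx, alt in enumerate(rec.ALT):
            for s_idx, sample in enumerate(samples):
                vaf = None
                if af_field is not None:
                    raw = np.atleast_1d(af_field[s_idx])
                    v = float(raw[min(alt_idx, len(raw) - 1)])
                    if np.isfinite(v) and v > 0:
                        vaf = v
                elif ad_field is not None:
                    ad = np.atleast_1d(ad_field[s_idx]).astype(float)
                    ref_d, alt_d = ad[0], ad[1 + alt_idx]
                    if alt_d > 0 and (ref_d + alt_d) > 0:
                        vaf = alt_d / (ref_d + alt_d)
                if vaf is None:
                    continue
                out.append(
                    AnnotatedVariant(
                        patient_id=sample,
                        chrom=str(rec.CHROM),
                        pos=int(rec.POS),
                        ref=str(rec.REF),
                        alt=str(alt),
                        vaf=float(vaf),
                        consequence=Consequence(str(consequence_raw).lower()),
                        protein_change=info.get("PCHANGE"),
                        gnomad_max_pop_af=_opt_float(
                            info.get("GNOMAD_MAX_AF"), "gnomAD AF"
                        ),
                        clinvar=(ClinVar(str(info["CLINVAR"]).lower())
                                 if "CLINVAR" in info else ClinVar.ABSENT),
                        oncokb=(OncoKB(str(info["ONCOKB"]).lower())
                                if "ONCOKB" in info else OncoKB.ABSENT),
                        alphamissense=(
                            AlphaMissense(str(info["AM_CLASS"]).lower())
                            if "AM_CLASS" in info else AlphaMissense.ABSENT
                        ),
                        alphamissense_score=_opt_float(
                            info.get("AM_SCORE"), "AlphaMissense score"
                        ),
                        cadd_phred=_opt_float(info.get("CADD_PHRED"), "CADD"),
                        in_germline_dataset=_opt_bool(info.get("GERMLINE_DB")),
                    )
                )
    return out


def read_variant_table(path: str, format: str = "auto") -> List[AnnotatedVariant]:
    """Read a variant table, auto-detecting VCF vs. TSV from the filename."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "auto":
        format = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf":
        return read_variant_vcf(path)
    if format == "tsv":
        return read_variant_tsv(path)
    raise ValueError(f"unknown variant table format {format!r}")


def variants_to_frame(variants: Iterable[AnnotatedVariant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        rows.append(
            {
                "patient_id": v.patient_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "protein_change": v.protein_change,
                "vaf": v.vaf,
                "consequence": v.consequence.value,
                "gnomad_max_pop_af": v.gnomad_max_pop_af,
                "clinvar": v.clinvar.value,
                "oncokb": v.oncokb.value,
                "alphamissense": v.alphamissense.value,
                "alphamissense_score": v.alphamissense_score,
                "cadd_phred": v.cadd_phred,
                "in_germline_dataset": int(v.in_germline_dataset),
                "paired_germline_call": v.paired_germline_call.value,
            }
        )
    return pd.DataFrame(rows, columns=_VARIANT_COLUMNS)


def write_table(frame: pd.DataFrame, path: str) -> None:
    """Write any table in the canonical dialect ('.' for missing)."""
    frame.to_csv(path, sep="\t", index=False, na_rep=".")


def write_variant_table(variants: Iterable[AnnotatedVariant], path: str) -> None:
    write_table(variants_to_frame(variants), path)


def classified_to_frame(classified: Iterable[ClassifiedVariant]) -> pd.DataFrame:
    base = variants_to_frame([cv.variant for cv in classified])
    base["label"] = [cv.label.value for cv in classified]
    base["tier"] = [cv.tier for cv in classified]
    base["deciding_rule"] = [cv.deciding_rule for cv in classified]
    return base


def write_classified_table(classified: Iterable[ClassifiedVariant], path: str) -> None:
    write_table(classified_to_frame(classified), path)


def read_classified_table(path: str) -> List[ClassifiedVariant]:
    from .types import Label

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    variants = variants_from_frame(frame)
    out = []
    for v, row in zip(variants, frame.to_dict("records")):
        out.append(
            ClassifiedVariant(
                variant=v,
                label=Label(row["label"]),
                tier=int(row["tier"]),
                deciding_rule=row["deciding_rule"],
            )
        )
    return out


def status_to_frame(statuses: Iterable[PatientAtmStatus]) -> pd.DataFrame:
    rows = []
    for s in statuses:
        rep = s.representative_variant
        rows.append(
            {
                "patient_id": s.patient_id,
                "atm_status": s.status,
                "n_somatic_mutations": s.n_somatic_mutations,
                "representative_change": rep.variant.key if rep else None,
                "representative_vaf": rep.variant.vaf if rep else None,
                "representative_tier": rep.tier if rep else None,
                "has_del11q": int(s.has_del11q),
                "del11q_known": int(s.del11q_known),
                "biallelic": int(s.biallelic),
                "cnloh_flag": int(s.cnloh_flag),
            }
        )
    return pd.DataFrame(rows)


def write_status_table(statuses: Iterable[PatientAtmStatus], path: str) -> None:
    write_table(status_to_frame(statuses), path)


def read_clinical_table(path: str) -> pd.DataFrame:
    """Read the per-patient clinical table (canonical dialect)."""
    frame = pd.read_csv(path, sep="\t", na_values=[".", ""])
    if "patient_id" not in frame.columns:
        raise ValueError("clinical table missing mandatory column 'patient_id'")
    frame["patient_id"] = frame["patient_id"].astype(str)
    return frame


def read_blocklist(path: str) -> Set[str]:
    """Germline-variant blocklist: one ``chrom:pos:ref:alt`` per line."""
    out: Set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
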