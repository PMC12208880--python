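"""Hierarchical evidence-tier classification of tumor-only ATM variants.

Tumor-only sequencing captures somatic mutations and germline variants in
the same read-out.  The flowchart implemented here triages each ATM variant
into ``somatic`` or ``germline_neutral`` by walking an ordered list of
evidence rules: known-germline datasets, paired tumor/germline calls,
population allele frequency (gnomAD), curated clinical annotation (ClinVar,
OncoKB), variant type, and in-silico pathogenicity predictors (AlphaMissense,
CADD).  The first rule that fires decides the label; the rule's position in
the hierarchy is the variant's evidence tier.

Downstream helpers harmonize recurrent variants across patients, collapse
variants to a per-patient ATM status (with copy-neutral-LOH flagging from the
VAF), and summarize VAF distributions per flowchart category.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import pandas as pd

from .types import (
    AlphaMissense,
    AnnotatedVariant,
    ClassifiedVariant,
    ClassifierConfig,
    ClinVar,
    Consequence,
    Label,
    NONSYNONYMOUS_CONSEQUENCES,
    OncoKB,
    PairedGermlineCall,
    PatientAtmStatus,
    TerminalRegion,
    TRUNCATING_CONSEQUENCES,
    ATM_PROTEIN_LENGTH,
)

__all__ = [
    "prefilter_variants",
    "classify_variant",
    "classify_cohort",
    "harmonize_recurrent_variants",
    "assign_patient_status",
    "vaf_distribution_summary",
    "terminal_region",
]


def prefilter_variants(
    variants: Iterable[AnnotatedVariant], cfg: ClassifierConfig
) -> List[AnnotatedVariant]:
    """Apply the up-front filters, preserving input order.

    Keeps variants with VAF >= ``min_vaf`` (inclusive), gnomAD max population
    AF strictly below ``common_polymorphism_af`` (absence from gnomAD passes),
    and an exonic non-synonymous or splice consequence.
    """
    kept = []
    for v in variants:
        if v.vaf < cfg.min_vaf:
            continue
        if v.gnomad_max_pop_af is not None and v.gnomad_max_pop_af >= cfg.common_polymorphism_af:
            continue
        if v.consequence not in NONSYNONYMOUS_CONSEQUENCES:
            continue
        kept.append(v)
    return kept


def _predictors_benign(v: AnnotatedVariant, cfg: ClassifierConfig) -> bool:
    """Both in-silico predictors point to a neutral impact."""
    am_benign = v.alphamissense is AlphaMissense.LIKELY_BENIGN
    cadd_benign = v.cadd_phred is not None and v.cadd_phred < cfg.cadd_pathogenic_cutoff
    return am_benign and cadd_benign


def _rule_germline_blocklist(v, cfg, blocklist):
    if v.in_germline_dataset or v.key in blocklist:
        return Label.GERMLINE_NEUTRAL
    return None


def _rule_paired_germline(v, cfg, blocklist):
    if v.paired_germline_call is PairedGermlineCall.CONFIRMED_GERMLINE:
        return Label.GERMLINE_NEUTRAL
    return None


def _rule_paired_somatic(v, cfg, blocklist):
    # A paired-sample somatic call short-circuits to somatic unless both
    # predictors suggest a neutral impact, in which case the variant falls
    # through to the evidence rules below.
    if v.paired_germline_call is PairedGermlineCall.CONFIRMED_SOMATIC:
        if not _predictors_benign(v, cfg):
            return Label.SOMATIC
    return None


def _rule_gnomad_rare_germline(v, cfg, blocklist):
    if v.gnomad_max_pop_af is not None and v.gnomad_max_pop_af > cfg.rare_germline_af:
        return Label.GERMLINE_NEUTRAL
    return None


def _rule_clinvar(v, cfg, blocklist):
    if v.clinvar in (ClinVar.PATHOGENIC, ClinVar.LIKELY_PATHOGENIC):
        return Label.SOMATIC
    if v.clinvar in (ClinVar.BENIGN, ClinVar.LIKELY_BENIGN):
        return Label.GERMLINE_NEUTRAL
    return None


def _rule_oncokb(v, cfg, blocklist):
    if v.oncokb in (OncoKB.ONCOGENIC, OncoKB.LIKELY_ONCOGENIC):
        return Label.SOMATIC
    return None


def _rule_truncating(v, cfg, blocklist):
    if v.consequence in TRUNCATING_CONSEQUENCES:
        return Label.SOMATIC
    return None


def _rule_insilico_predictors(v, cfg, blocklist):
    am = v.alphamissense
    cadd_high = v.cadd_phred is not None and v.cadd_phred >= cfg.cadd_pathogenic_cutoff
    if am is AlphaMissense.LIKELY_PATHOGENIC or cadd_high:
        return Label.SOMATIC
    if _predictors_benign(v, cfg):
        return Label.GERMLINE_NEUTRAL
    return None


def _rule_fallback(v, cfg, blocklist):
    # Conservative default for discordant or absent evidence: do not inflate
    # the mutated-patient count.
    return Label.GERMLINE_NEUTRAL


_RULES = {
    "germline_blocklist": _rule_germline_blocklist,
    "paired_germline": _rule_paired_germline,
    "paired_somatic": _rule_paired_somatic,
    "gnomad_rare_germline": _rule_gnomad_rare_germline,
    "clinvar": _rule_clinvar,
    "oncokb": _rule_oncokb,
    "truncating": _rule_truncating,
    "insilico_predictors": _rule_insilico_predictors,
    "fallback": _rule_fallback,
}

#: For each label, the earliest default-tier rule that can emit it; used to
#: break exact tier ties during cohort harmonization.
_FIRST_EMITTING_RULE = {
    Label.GERMLINE_NEUTRAL: "germline_blocklist",
    Label.SOMATIC: "paired_somatic",
}


def classify_variant(
    v: AnnotatedVariant,
    cfg: ClassifierConfig,
    germline_blocklist: Optional[Set[str]] = None,
) -> ClassifiedVariant:
    """Run the flowchart on one pre-filtered variant.

    Pure and deterministic: the label and tier depend only on the variant,
    the configuration and the blocklist.  The fallback rule guarantees a
    verdict even when every evidence field is absent (such calls carry
    ``low_evidence=True``).
    """
    blocklist = germline_blocklist or set()
    for tier, rule_name in enumerate(cfg.tier_order):
        try:
            rule = _RULES[rule_name]
        except KeyError:
            raise ValueError(f"unknown flowchart rule {rule_name!r}") from None
        label = rule(v, cfg, blocklist)
        if label is not None:
            return ClassifiedVariant(variant=v, label=label, tier=tier,
                                     deciding_rule=rule_name)
    raise ValueError(
        "tier_order exhausted without a verdict; include the 'fallback' rule"
    )


def classify_cohort(
    variants: Iterable[AnnotatedVariant],
    cfg: Optional[ClassifierConfig] = None,
    germline_blocklist: Optional[Set[str]] = None,
    prefilter: bool = True,
    harmonize: bool = True,
) -> List[ClassifiedVariant]:
    """Pre-filter, classify and (optionally) harmonize a whole cohort."""
    cfg = cfg or ClassifierConfig()
    vs = list(variants)
    if prefilter:
        vs = prefilter_variants(vs, cfg)
    classified = [classify_variant(v, cfg, germline_blocklist) for v in vs]
    if harmonize:
        classified = harmonize_recurrent_variants(classified, cfg)
    return classified


def harmonize_recurrent_variants(
    classified: Sequence[ClassifiedVariant],
    cfg: Optional[ClassifierConfig] = None,
) -> List[ClassifiedVariant]:
    """Give every occurrence of an identical genomic change one label.

    Identical variants can be classified differently across patients when a
    patient-level field (paired germline call, VAF-independent annotations
    injected per-center) differs.  All occurrences are reassigned the verdict
    whose deciding rule sits highest in the hierarchy (smallest tier).  An
    exact tier tie between conflicting labels resolves to the label whose
    first emitting rule appears earlier in the tier order, which makes the
    outcome independent of input order.  Idempotent.
    """
    cfg = cfg or ClassifierConfig()
    order = list(cfg.tier_order)

    def _label_rank(label: Label) -> int:
        rule = _FIRST_EMITTING_RULE[label]
        return order.index(rule) if rule in order else len(order)

    by_key: Dict[str, List[ClassifiedVariant]] = defaultdict(list)
    for cv in classified:
        by_key[cv.variant.key].append(cv)

    winners: Dict[str, ClassifiedVariant] = {}
    for key, occurrences in by_key.items():
        winners[key] = min(
            occurrences,
            key=lambda cv: (cv.tier, _label_rank(cv.label)),
        )

    out = []
    for cv in classified:
        w = winners[cv.variant.key]
        if cv.label == w.label and cv.tier == w.tier and cv.deciding_rule == w.deciding_rule:
            out.append(cv)
        else:
            out.append(
                ClassifiedVariant(variant=cv.variant, label=w.label,
                                  tier=w.tier, deciding_rule=w.deciding_rule)
            )
    return out


def _representative(somatic: List[ClassifiedVariant]) -> ClassifiedVariant:
    # Highest hierarchical rank first; within a tier the highest VAF; residual
    # ties broken by genomic coordinate for determinism.
    return min(
        somatic,
        key=lambda cv: (cv.tier, -cv.variant.vaf, cv.variant.coordinate),
    )


def assign_patient_status(
    classified: Sequence[ClassifiedVariant],
    del11q_flags: Mapping[str, bool],
    cfg: Optional[ClassifierConfig] = None,
) -> List[PatientAtmStatus]:
    """Collapse classified variants to one ATM status per patient.

    Patients with at least one somatic-labeled variant are ``mutated``;
    patients carrying only germline/neutral variants are re-categorized as
    ``wildtype``.  The representative variant is the somatic variant with the
    smallest tier, ties broken by largest VAF then genomic coordinate.
    ``cnloh_flag`` is set when the representative VAF exceeds the high-VAF
    threshold in a patient without del(11q).  Patients absent from
    ``del11q_flags`` get unknown-safe ``False`` flags and a warning.
    """
    cfg = cfg or ClassifierConfig()
    by_patient: Dict[str, List[ClassifiedVariant]] = defaultdict(list)
    for cv in classified:
        by_patient[cv.variant.patient_id].append(cv)

    statuses = []
    for pid in sorted(by_patient):
        cvs = by_patient[pid]
        if pid in del11q_flags:
            del11q = bool(del11q_flags[pid])
            known = True
        else:
            warnings.warn(
                f"patient {pid!r} missing from del(11q) flags; "
                "cnLOH and biallelic flags set to False",
                stacklevel=2,
            )
            del11q, known = False, False
        somatic = [cv for cv in cvs if cv.label is Label.SOMATIC]
        if somatic:
            rep = _representative(somatic)
            cnloh = known and not del11q and rep.variant.vaf > cfg.high_vaf_threshold
            statuses.append(
                PatientAtmStatus(
                    patient_id=pid,
                    status="mutated",
                    n_somatic_mutations=len(somatic),
                    representative_variant=rep,
                    has_del11q=del11q,
                    biallelic=del11q,
                    cnloh_flag=cnloh,
                    del11q_known=known,
                )
            )
        else:
            statuses.append(
                PatientAtmStatus(
                    patient_id=pid,
                    status="wildtype",
                    n_somatic_mutations=0,
                    representative_variant=None,
                    has_del11q=del11q,
                    biallelic=False,
                    cnloh_flag=False,
                    del11q_known=known,
                )
            )
    return statuses


def vaf_distribution_summary(
    classified: Sequence[ClassifiedVariant],
    del11q_flags: Mapping[str, bool],
) -> pd.DataFrame:
    """Per-label and per-flowchart-category VAF summaries.

    For each (label, deciding rule) group and for each label overall, reports
    the variant count, median VAF, the fraction of variants with VAF strictly
    above 0.5, and — among those high-VAF variants — the fraction occurring
    in del(11q)-positive patients.  Empty groups report count 0 with absent
    (pd.NA) statistics rather than NaN propagation.
    """
    if not classified:
        raise ValueError("vaf_distribution_summary requires a nonempty cohort")

    rows = []
    records = pd.DataFrame(
        {
            "label": [cv.label.value for cv in classified],
            "category": [cv.deciding_rule for cv in classified],
            "vaf": [cv.variant.vaf for cv in classified],
            "del11q": [
                bool(del11q_flags.get(cv.variant.patient_id, False))
                for cv in classified
            ],
        }
    )

    def _summarize(group: pd.DataFrame, label: str, category: str) -> dict:
        n = len(group)
        if n == 0:
            return {
                "label": label, "category": category, "count": 0,
                "median_vaf": pd.NA, "frac_vaf_gt_50": pd.NA,
                "frac_high_vaf_in_del11q": pd.NA,
            }
        high = group[group["vaf"] > 0.5]
        return {
            "label": label,
            "category": category,
            "count": n,
            "median_vaf": float(group["vaf"].median()),
            "frac_vaf_gt_50": len(high) / n,
            "frac_high_vaf_in_del11q": (
                float(high["del11q"].mean()) if len(high) else pd.NA
            ),
        }

    for (label, category), group in records.groupby(["label", "category"]):
        rows.append(_summarize(group, label, category))
    for label, group in records.groupby("label"):
        rows.append(_summarize(group, label, "all"))
    return pd.DataFrame(rows).sort_values(["label", "category"]).reset_index(drop=True)


def terminal_region(protein_position: int, fat_start: int = 1960) -> TerminalRegion:
    """Assign a protein position to the N- or C-terminal region of ATM.

    The C-terminal region starts at the first residue of the FAT domain
    (boundary inclusive); everything upstream is N-terminal.
    """
    if not 1 <= protein_position <= ATM_PROTEIN_LENGTH:
        raise ValueError(
            f"protein position {protein_position} outside 1..{ATM_PROTEIN_LENGTH}"
        )
    if protein_position >= fat_start:
        return TerminalRegion.C_TERMINAL
    return TerminalRegion.N_TERMINAL
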