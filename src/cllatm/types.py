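"""Core domain types for tumor-only ATM variant triage.

The central objects are :class:`AnnotatedVariant` (one variant observation in
one patient, carrying all annotation evidence used by the classification
flowchart), :class:`ClassifiedVariant` (the variant plus its evidence tier and
somatic vs. germline/neutral label) and :class:`PatientAtmStatus` (the
per-patient ATM call derived from the classified variants).

All coordinates are GRCh37, 1-based, fully closed; protein changes refer to
the ATM reference transcript NM_000051.3.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

ATM_PROTEIN_LENGTH = 3056
#: First residue of the FAT domain (UniProt Q13315 annotation); positions at
#: or beyond this residue are called C-terminal.
DEFAULT_FAT_START = 1960


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Consequence classes retained by the pre-filter (exonic non-synonymous
#: variants and small insertions/deletions, plus splice-site changes).
NONSYNONYMOUS_CONSEQUENCES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
        Consequence.SPLICE,
    }
)

TRUNCATING_CONSEQUENCES = frozenset(
    {Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.SPLICE}
)


class ClinVar(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    CONFLICTING = "conflicting"
    ABSENT = "absent"


class OncoKB(str, enum.Enum):
    ONCOGENIC = "oncogenic"
    LIKELY_ONCOGENIC = "likely_oncogenic"
    VUS = "vus"
    LIKELY_NEUTRAL = "likely_neutral"
    ABSENT = "absent"


class AlphaMissense(str, enum.Enum):
    LIKELY_PATHOGENIC = "likely_pathogenic"
    AMBIGUOUS = "ambiguous"
    LIKELY_BENIGN = "likely_benign"
    ABSENT = "absent"


class PairedGermlineCall(str, enum.Enum):
    CONFIRMED_SOMATIC = "confirmed_somatic"
    CONFIRMED_GERMLINE = "confirmed_germline"
    UNKNOWN = "unknown"


class Label(str, enum.Enum):
    SOMATIC = "somatic"
    GERMLINE_NEUTRAL = "germline_neutral"


class TerminalRegion(str, enum.Enum):
    N_TERMINAL = "N_terminal"
    C_TERMINAL = "C_terminal"


class MalformedVariantError(ValueError):
    """Raised when a variant record violates a domain invariant."""


@dataclass(frozen=True)
class AnnotatedVariant:
    """One variant observation in one patient with all annotation evidence.

    ``gnomad_max_pop_af`` is the maximum allele frequency across gnomAD
    ancestry groups; ``None`` means the variant was not observed in gnomAD,
    which the classifier treats as evidence against common germline origin.
    """

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    consequence: Consequence
    protein_change: Optional[str] = None
    gnomad_max_pop_af: Optional[float] = None
    clinvar: ClinVar = ClinVar.ABSENT
    oncokb: OncoKB = OncoKB.ABSENT
    alphamissense: AlphaMissense = AlphaMissense.ABSENT
    alphamissense_score: Optional[float] = None
    cadd_phred: Optional[float] = None
    in_germline_dataset: bool = False
    paired_germline_call: PairedGermlineCall = PairedGermlineCall.UNKNOWN

    def __post_init__(self) -> None:
        if not (isinstance(self.vaf, (int, float)) and math.isfinite(self.vaf)
                and 0.0 <= self.vaf <= 1.0):
            raise MalformedVariantError(
                f"{self.patient_id} {self.key}: VAF {self.vaf!r} outside [0, 1]"
            )
        if self.pos < 1:
            raise MalformedVariantError(
                f"{self.patient_id} {self.key}: position must be >= 1"
            )
        if self.ref == self.alt:
            raise MalformedVariantError(
                f"{self.patient_id} {self.key}: ref equals alt"
            )
        if self.gnomad_max_pop_af is not None and not (
            0.0 <= self.gnomad_max_pop_af <= 1.0
        ):
            raise MalformedVariantError(
                f"{self.patient_id} {self.key}: gnomAD AF "
                f"{self.gnomad_max_pop_af!r} outside [0, 1]"
            )

    @property
    def key(self) -> str:
        """Genomic change as ``chrom:pos:ref:alt`` (GRCh37, 1-based)."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def coordinate(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


# Flowchart rule names, strongest somatic/germline evidence first.  The order
# is the default evidence hierarchy; it is configurable via
# ``ClassifierConfig.tier_order``.
DEFAULT_TIER_ORDER: tuple = (
    "germline_blocklist",
    "paired_germline",
    "paired_somatic",
    "gnomad_rare_germline",
    "clinvar",
    "oncokb",
    "truncating",
    "insilico_predictors",
    "fallback",
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and rule ordering for the classification flowchart.

    Defaults: variants with VAF below 5% are discarded; gnomAD max population
    AF of 1% or more marks a common polymorphism (excluded up front); AF above
    0.001 marks a rare germline variant; CADD phred 20 (top 1% of variants) is
    the in-silico pathogenicity cutoff; representative somatic VAFs above 60%
    in patients without del(11q) flag possible copy-neutral LOH.
    """

    min_vaf: float = 0.05
    common_polymorphism_af: float = 0.01
    rare_germline_af: float = 0.001
    cadd_pathogenic_cutoff: float = 20.0
    high_vaf_threshold: float = 0.60
    tier_order: Sequence[str] = DEFAULT_TIER_ORDER

    def __post_init__(self) -> None:
        if not (0.0 < self.rare_germline_af < self.common_polymorphism_af < 1.0):
            raise ValueError(
                "require 0 < rare_germline_af < common_polymorphism_af < 1"
            )
        if not (0.0 < self.min_vaf < self.high_vaf_threshold < 1.0):
            raise ValueError("require 0 < min_vaf < high_vaf_threshold < 1")
        if len(set(self.tier_order)) != len(self.tier_order):
            raise ValueError("tier_order contains duplicate rule names")

    def tier_of(self, rule: str) -> int:
        return list(self.tier_order).index(rule)


@dataclass(frozen=True)
class ClassifiedVariant:
    """A variant plus the flowchart's verdict.

    ``tier`` is the index of ``deciding_rule`` in the configured tier order
    (lower = stronger evidence).  ``low_evidence`` marks variants that only
    the fallback rule could place.
    """

    variant: AnnotatedVariant
    label: Label
    tier: int
    deciding_rule: str

    @property
    def low_evidence(self) -> bool:
        return self.deciding_rule == "fallback"


@dataclass(frozen=True)
class PatientAtmStatus:
    """Per-patient ATM call after variant-level classification.

    A patient is ``mutated`` iff they carry at least one somatic-labeled
    variant; patients whose variants are all germline/neutral are re-assigned
    to wildtype.  ``biallelic`` means a somatic mutation together with
    del(11q); ``cnloh_flag`` marks mutated patients whose representative VAF
    exceeds the high-VAF threshold without del(11q), the signature of
    copy-neutral loss of heterozygosity.
    """

    patient_id: str
    status: str  # "wildtype" | "mutated"
    n_somatic_mutations: int
    representative_variant: Optional[ClassifiedVariant]
    has_del11q: bool
    biallelic: bool
    cnloh_flag: bool
    del11q_known: bool = True

    def __post_init__(self) -> None:
        if (self.status == "mutated") != (self.n_somatic_mutations >= 1):
            raise ValueError("status mutated iff >= 1 somatic mutation")
        if (self.representative_variant is not None) != (self.status == "mutated"):
            raise ValueError("representative variant present iff mutated")
        if self.biallelic and not (self.status == "mutated" and self.has_del11q):
            raise ValueError("biallelic requires mutated status and del(11q)")
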