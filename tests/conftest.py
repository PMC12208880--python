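import numpy as np
import pytest

from cllatm.types import (
    AlphaMissense,
    AnnotatedVariant,
    ClassifierConfig,
    ClinVar,
    Consequence,
    OncoKB,
    PairedGermlineCall,
)


def make_variant(
    patient_id="P1",
    chrom="11",
    pos=108_100_000,
    ref="A",
    alt="T",
    vaf=0.30,
    consequence=Consequence.MISSENSE,
    protein_change=None,
    gnomad_max_pop_af=None,
    clinvar=ClinVar.ABSENT,
    oncokb=OncoKB.ABSENT,
    alphamissense=AlphaMissense.ABSENT,
    alphamissense_score=None,
    cadd_phred=None,
    in_germline_dataset=False,
    paired_germline_call=PairedGermlineCall.UNKNOWN,
):
    return AnnotatedVariant(
        patient_id=patient_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        vaf=vaf,
        consequence=consequence,
        protein_change=protein_change,
        gnomad_max_pop_af=gnomad_max_pop_af,
        clinvar=clinvar,
        oncokb=oncokb,
        alphamissense=alphamissense,
        alphamissense_score=alphamissense_score,
        cadd_phred=cadd_phred,
        in_germline_dataset=in_germline_dataset,
        paired_germline_call=paired_germline_call,
    )


@pytest.fixture
def cfg():
    return ClassifierConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
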