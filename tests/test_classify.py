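"""Unit and property tests for the variant-classification flowchart."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cllatm.classify import (
    assign_patient_status,
    classify_variant,
    harmonize_recurrent_variants,
    prefilter_variants,
    terminal_region,
    vaf_distribution_summary,
)
from cllatm.types import (
    AlphaMissense,
    ClassifierConfig,
    ClinVar,
    Consequence,
    Label,
    MalformedVariantError,
    OncoKB,
    PairedGermlineCall,
    TerminalRegion,
)

from conftest import make_variant


class TestPrefilter:
    @pytest.mark.parametrize(
        "kwargs, kept",
        [
            ({"vaf": 0.04}, False),                     # below the 5% VAF floor
            ({"vaf": 0.05}, True),                      # floor is inclusive
            ({"consequence": Consequence.SYNONYMOUS, "vaf": 0.40}, False),
            ({"consequence": Consequence.MISSENSE, "vaf": 0.40}, True),
            ({"gnomad_max_pop_af": 0.02}, False),       # common polymorphism
            ({"gnomad_max_pop_af": 0.009}, True),
            ({"gnomad_max_pop_af": None}, True),        # absence passes
            ({"consequence": Consequence.OTHER}, False),
            ({"consequence": Consequence.FRAMESHIFT}, True),
        ],
    )
    def test_filter_rules(self, cfg, kwargs, kept):
        v = make_variant(**kwargs)
        assert (prefilter_variants([v], cfg) == [v]) is kept

    def test_order_preserved(self, cfg):
        vs = [make_variant(patient_id=f"P{i}", pos=100 + i) for i in range(5)]
        assert prefilter_variants(vs, cfg) == vs

    def test_malformed_vaf_rejected(self):
        with pytest.raises(MalformedVariantError, match="VAF"):
            make_variant(vaf=1.5)

    @given(
        min_vaf=st.floats(0.01, 0.5),
        common_af=st.floats(0.002, 0.9),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_tightening_thresholds_is_monotone(self, min_vaf, common_af, data):
        """Raising min_vaf or lowering the polymorphism cutoff never keeps more."""
        vs = [
            make_variant(
                patient_id=f"P{i}",
                vaf=data.draw(st.floats(0.0, 1.0)),
                gnomad_max_pop_af=data.draw(
                    st.one_of(st.none(), st.floats(0.0, 0.05))
                ),
            )
            for i in range(10)
        ]
        loose = ClassifierConfig(min_vaf=0.01, common_polymorphism_af=0.9)
        tight = ClassifierConfig(min_vaf=max(min_vaf, 0.01),
                                 common_polymorphism_af=min(common_af, 0.9))
        assert len(prefilter_variants(vs, tight)) <= len(prefilter_variants(vs, loose))


class TestClassifyVariant:
    def test_rare_germline_af_rule(self, cfg):
        v = make_variant(gnomad_max_pop_af=0.005)
        cv = classify_variant(v, cfg)
        assert cv.label is Label.GERMLINE_NEUTRAL
        assert cv.deciding_rule == "gnomad_rare_germline"

    def test_truncating_rule(self, cfg):
        v = make_variant(consequence=Consequence.FRAMESHIFT, vaf=0.32)
        cv = classify_variant(v, cfg)
        assert cv.label is Label.SOMATIC
        assert cv.deciding_rule == "truncating"

    def test_oncokb_hotspot_missense(self, cfg):
        # the recurrent kinase-domain missense p.R3008C: oncogenic in OncoKB
        v = make_variant(protein_change="p.R3008C", oncokb=OncoKB.ONCOGENIC)
        cv = classify_variant(v, cfg)
        assert cv.label is Label.SOMATIC
        assert cv.deciding_rule == "oncokb"

    @pytest.mark.parametrize(
        "kwargs, rule, label",
        [
            ({"in_germline_dataset": True}, "germline_blocklist",
             Label.GERMLINE_NEUTRAL),
            ({"paired_germline_call": PairedGermlineCall.CONFIRMED_GERMLINE},
             "paired_germline", Label.GERMLINE_NEUTRAL),
            ({"paired_germline_call": PairedGermlineCall.CONFIRMED_SOMATIC},
             "paired_somatic", Label.SOMATIC),
            ({"clinvar": ClinVar.PATHOGENIC}, "clinvar", Label.SOMATIC),
            ({"clinvar": ClinVar.BENIGN}, "clinvar", Label.GERMLINE_NEUTRAL),
            ({"alphamissense": AlphaMissense.LIKELY_PATHOGENIC},
             "insilico_predictors", Label.SOMATIC),
            ({"cadd_phred": 25.0}, "insilico_predictors", Label.SOMATIC),
            ({"alphamissense": AlphaMissense.LIKELY_BENIGN, "cadd_phred": 5.0},
             "insilico_predictors", Label.GERMLINE_NEUTRAL),
        ],
    )
    def test_single_rule_decisions(self, cfg, kwargs, rule, label):
        cv = classify_variant(make_variant(**kwargs), cfg)
        assert cv.deciding_rule == rule
        assert cv.label is label
        assert cv.tier == cfg.tier_of(rule)

    def test_blocklist_membership(self, cfg):
        v = make_variant(clinvar=ClinVar.PATHOGENIC)
        cv = classify_variant(v, cfg, germline_blocklist={v.key})
        assert cv.label is Label.GERMLINE_NEUTRAL
        assert cv.deciding_rule == "germline_blocklist"

    def test_confirmed_somatic_overridden_by_benign_predictors(self, cfg):
        # paired-sample somatic calls are reclassified when both predictors
        # point to a neutral impact
        v = make_variant(
            paired_germline_call=PairedGermlineCall.CONFIRMED_SOMATIC,
            alphamissense=AlphaMissense.LIKELY_BENIGN,
            cadd_phred=3.0,
        )
        cv = classify_variant(v, cfg)
        assert cv.label is Label.GERMLINE_NEUTRAL
        assert cv.deciding_rule == "insilico_predictors"

    def test_all_evidence_absent_falls_back_low_evidence(self, cfg):
        cv = classify_variant(make_variant(), cfg)
        assert cv.label is Label.GERMLINE_NEUTRAL
        assert cv.deciding_rule == "fallback"
        assert cv.low_evidence

    def test_deterministic_pure_function(self, cfg):
        v = make_variant(cadd_phred=30.0)
        results = {classify_variant(v, cfg) for _ in range(5)}
        assert len(results) == 1


class TestHarmonize:
    def test_smallest_tier_wins(self, cfg):
        v1 = make_variant(patient_id="P1", oncokb=OncoKB.ONCOGENIC)
        v2 = make_variant(patient_id="P2")  # same genomic change, no evidence
        cvs = [classify_variant(v, cfg) for v in (v1, v2)]
        assert {cv.label for cv in cvs} == {Label.SOMATIC, Label.GERMLINE_NEUTRAL}
        out = harmonize_recurrent_variants(cvs, cfg)
        assert all(cv.label is Label.SOMATIC for cv in out)
        assert all(cv.deciding_rule == "oncokb" for cv in out)

    def test_no_conflict_is_identity(self, cfg):
        cvs = [
            classify_variant(make_variant(patient_id=p, pos=200 + i), cfg)
            for i, p in enumerate(["P1", "P2"])
        ]
        assert harmonize_recurrent_variants(cvs, cfg) == cvs

    def test_idempotent(self, cfg):
        cvs = [
            classify_variant(make_variant(patient_id="P1", cadd_phred=30.0), cfg),
            classify_variant(make_variant(patient_id="P2"), cfg),
        ]
        once = harmonize_recurrent_variants(cvs, cfg)
        assert harmonize_recurrent_variants(once, cfg) == once

    def test_equal_tier_conflict_stable_under_permutation(self, cfg):
        # same genomic change decided by the same (clinvar) tier with
        # opposite labels: resolution must not depend on input order
        v_som = make_variant(patient_id="P1", clinvar=ClinVar.PATHOGENIC)
        v_ben = make_variant(patient_id="P2", clinvar=ClinVar.BENIGN)
        others = [
            classify_variant(make_variant(patient_id="P3", pos=999), cfg)
        ]
        cvs = [classify_variant(v, cfg) for v in (v_som, v_ben)] + others
        labels = set()
        for perm in itertools.permutations(cvs):
            out = harmonize_recurrent_variants(list(perm), cfg)
            resolved = {cv.label for cv in out if cv.variant.pos != 999}
            assert len(resolved) == 1
            labels.add(next(iter(resolved)))
        assert len(labels) == 1


def brute_force_representative(somatic):
    """Oracle: scan all orderings and pick by (tier, -vaf, coordinate)."""
    best = None
    for cv in somatic:
        key = (cv.tier, -cv.variant.vaf, cv.variant.coordinate)
        if best is None or key < best[0]:
            best = (key, cv)
    return best[1]


class TestAssignPatientStatus:
    def _classify(self, cfg, *variants):
        return [classify_variant(v, cfg) for v in variants]

    def test_rank_beats_vaf(self, cfg):
        cvs = self._classify(
            cfg,
            make_variant(pos=1, vaf=0.20, consequence=Consequence.NONSENSE),
            make_variant(pos=2, vaf=0.10, clinvar=ClinVar.PATHOGENIC),
        )
        (status,) = assign_patient_status(cvs, {"P1": False}, cfg)
        assert status.representative_variant.variant.pos == 2  # clinvar tier

    def test_same_tier_highest_vaf(self, cfg):
        cvs = self._classify(
            cfg,
            make_variant(pos=1, vaf=0.45, consequence=Consequence.NONSENSE),
            make_variant(pos=2, vaf=0.12, consequence=Consequence.FRAMESHIFT),
        )
        (status,) = assign_patient_status(cvs, {"P1": False}, cfg)
        assert status.representative_variant.variant.vaf == 0.45

    def test_only_germline_variants_is_wildtype(self, cfg):
        cvs = self._classify(cfg, make_variant(gnomad_max_pop_af=0.005))
        (status,) = assign_patient_status(cvs, {"P1": False}, cfg)
        assert status.status == "wildtype"
        assert status.representative_variant is None
        assert not status.biallelic

    def test_cnloh_flag_high_vaf_without_del11q(self, cfg):
        cvs = self._classify(
            cfg, make_variant(vaf=0.71, consequence=Consequence.NONSENSE)
        )
        (status,) = assign_patient_status(cvs, {"P1": False}, cfg)
        assert status.cnloh_flag
        (status,) = assign_patient_status(cvs, {"P1": True}, cfg)
        assert not status.cnloh_flag
        assert status.biallelic

    def test_missing_del11q_flag_warns_and_is_safe(self, cfg):
        cvs = self._classify(
            cfg, make_variant(vaf=0.71, consequence=Consequence.NONSENSE)
        )
        with pytest.warns(UserWarning, match="del\\(11q\\)"):
            (status,) = assign_patient_status(cvs, {}, cfg)
        assert not status.cnloh_flag and not status.biallelic
        assert not status.del11q_known

    def test_partition_of_cohort(self, cfg, rng):
        # every patient ends up exactly once, wildtype or mutated
        cvs = []
        for i in range(30):
            cvs.append(
                classify_variant(
                    make_variant(
                        patient_id=f"P{i}",
                        pos=1000 + i,
                        vaf=float(rng.uniform(0.05, 0.6)),
                        consequence=(
                            Consequence.NONSENSE if rng.random() < 0.5
                            else Consequence.MISSENSE
                        ),
                    ),
                    cfg,
                )
            )
        statuses = assign_patient_status(
            cvs, {f"P{i}": False for i in range(30)}, cfg
        )
        assert len(statuses) == 30
        assert all(s.status in ("wildtype", "mutated") for s in statuses)

    def test_representative_matches_brute_force_oracle(self, cfg, rng):
        # random small cohorts, implementation vs exhaustive scan
        for _ in range(50):
            n = int(rng.integers(1, 21))
            cvs = []
            for i in range(n):
                pid = f"P{int(rng.integers(0, 4))}"
                kwargs = {}
                choice = rng.integers(0, 4)
                if choice == 0:
                    kwargs["consequence"] = Consequence.NONSENSE
                elif choice == 1:
                    kwargs["clinvar"] = ClinVar.PATHOGENIC
                elif choice == 2:
                    kwargs["oncokb"] = OncoKB.ONCOGENIC
                else:
                    kwargs["cadd_phred"] = 30.0
                cvs.append(
                    classify_variant(
                        make_variant(
                            patient_id=pid,
                            pos=int(rng.integers(1, 10_000)),
                            vaf=round(float(rng.uniform(0.05, 0.9)), 3),
                            **kwargs,
                        ),
                        cfg,
                    )
                )
            flags = {f"P{i}": False for i in range(4)}
            statuses = assign_patient_status(cvs, flags, cfg)
            for s in statuses:
                somatic = [
                    cv for cv in cvs
                    if cv.variant.patient_id == s.patient_id
                    and cv.label is Label.SOMATIC
                ]
                if somatic:
                    assert s.representative_variant == brute_force_representative(somatic)


class TestVafSummary:
    def test_boundary_half_is_exclusive(self, cfg):
        cvs = [
            classify_variant(
                make_variant(patient_id=f"P{i}", pos=10 + i, vaf=0.5,
                             gnomad_max_pop_af=0.005),
                cfg,
            )
            for i in range(4)
        ]
        summary = vaf_distribution_summary(cvs, {f"P{i}": False for i in range(4)})
        row = summary[(summary.label == "germline_neutral") & (summary.category == "all")]
        assert float(row.frac_vaf_gt_50.iloc[0]) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            vaf_distribution_summary([], {})

    def test_generator_consistent_medians(self, cfg):
        # germline VAFs ~ truncated Normal(0.5, 0.04): median near 0.5;
        # somatic model keeps the bulk below 0.5
        from cllatm.simulate import CohortSimConfig, simulate_patients, simulate_variants
        from cllatm.io import variants_from_frame
        from cllatm.classify import classify_cohort

        sim = CohortSimConfig(n_patients=6000, seed=7, decoy_fraction=0.10)
        r = sim.rng()
        _, truth = simulate_patients(sim, r)
        variants, _ = simulate_variants(truth, sim, r)
        cvs = classify_cohort(variants_from_frame(variants))
        flags = dict(zip(truth.patient_id, truth.del11q.astype(bool)))
        summary = vaf_distribution_summary(cvs, flags)
        germ = summary[(summary.label == "germline_neutral") & (summary.category == "all")]
        som = summary[(summary.label == "somatic") & (summary.category == "all")]
        assert germ["count"].iloc[0] >= 500
        assert 0.49 <= float(germ.median_vaf.iloc[0]) <= 0.51
        assert float(som.frac_vaf_gt_50.iloc[0]) < 0.2


class TestTerminalRegion:
    @pytest.mark.parametrize(
        "pos, region",
        [
            (468, TerminalRegion.N_TERMINAL),    # p.K468fs
            (3008, TerminalRegion.C_TERMINAL),   # p.R3008C
            (1960, TerminalRegion.C_TERMINAL),   # FAT start, inclusive
            (1959, TerminalRegion.N_TERMINAL),
        ],
    )
    def test_fat_domain_boundary(self, pos, region):
        assert terminal_region(pos) is region

    @pytest.mark.parametrize("pos", [0, -5, 3057])
    def test_out_of_range_rejected(self, pos):
        with pytest.raises(ValueError):
            terminal_region(pos)
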