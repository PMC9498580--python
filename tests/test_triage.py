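"""Composite deleteriousness classification and genotype bookkeeping."""

import dataclasses
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ciliavar.errors import InsufficientAnnotationError, ValidationError
from ciliavar.models import Cohort, PredictorProfile, VariantRecord
from ciliavar.triage import (
    allele_count,
    annotation_consistency_report,
    classify_variant,
    filter_variants,
    predictor_abnormalities,
    summarize_gene_genotype,
)


def make_record(**kwargs):
    defaults = dict(
        patient_id="P1",
        gene="DNAH9",
        dbsnp="rs1",
        nt_change="c.1A>G",
        consequence="missense",
        predictors=PredictorProfile(
            sift_label="D", pp2_humdiv_label="PD", ma_label="M"
        ),
        allele_freq=0.01,
        zygosity="het",
        panel="motile",
        clinical_class="VUS",
        inheritance="AR",
    )
    defaults.update(kwargs)
    return VariantRecord(**defaults)


class TestPredictorAbnormalities:
    def test_pp2_only_profile(self):
        # KMT2D p.P183S-like: tolerated SIFT, damaging PolyPhen2, neutral MA
        profile = PredictorProfile(
            sift_label="T", sift_score=0.62,
            pp2_humdiv_label="PD", pp2_humdiv_score=0.959,
            pp2_humvar_label="PD", pp2_humvar_score=0.6,
            ma_label="N", ma_score=0.55,
        )
        assert predictor_abnormalities(profile) == {"PP2"}

    def test_fully_benign_profile(self):
        # KDM6A p.R78C-like
        profile = PredictorProfile(
            sift_label="T", sift_score=0.15,
            pp2_humdiv_label="B", pp2_humdiv_score=0.05,
            pp2_humvar_label="B", pp2_humvar_score=0.009,
            ma_label="L", ma_score=1.31,
        )
        assert predictor_abnormalities(profile) == frozenset()

    def test_all_three_abnormal(self):
        profile = PredictorProfile(
            sift_label="D", pp2_humdiv_label="PD", pp2_humvar_label="PD", ma_label="H"
        )
        assert predictor_abnormalities(profile) == {"SIFT", "PP2", "MA"}

    def test_humvar_alone_counts_as_pp2(self):
        profile = PredictorProfile(
            sift_label="T", pp2_humdiv_label="B", pp2_humvar_label="D", ma_label="N"
        )
        assert predictor_abnormalities(profile) == {"PP2"}

    def test_sift_label_trusted_over_score(self):
        # MEGF8 p.R782W-like: printed D (0.085) although 0.085 > 0.05
        profile = PredictorProfile(sift_label="D", sift_score=0.085, ma_label="N")
        assert "SIFT" in predictor_abnormalities(profile)

    def test_sift_score_fallback_without_label(self):
        assert predictor_abnormalities(
            PredictorProfile(sift_score=0.01)
        ) == {"SIFT"}
        assert predictor_abnormalities(
            PredictorProfile(sift_score=0.2)
        ) == frozenset()

    def test_no_annotation_raises(self):
        with pytest.raises(InsufficientAnnotationError):
            predictor_abnormalities(PredictorProfile(cadd_phred=30.0))


class TestClassifyVariant:
    def test_novel_missense_single_abnormality_is_deleterious(self):
        record = make_record(
            dbsnp="New",
            allele_freq=None,
            predictors=PredictorProfile(
                sift_label="T", pp2_humdiv_label="PD", pp2_humvar_label="PD",
                ma_label="N",
            ),
        )
        call = classify_variant(record)
        assert call.deleterious and call.rule_fired == "missense_novel_one"

    def test_known_missense_needs_two_abnormalities(self):
        record = make_record(
            predictors=PredictorProfile(
                sift_label="T", pp2_humdiv_label="PD", pp2_humvar_label="PD",
                ma_label="N",
            )
        )
        assert not classify_variant(record).deleterious

    @pytest.mark.parametrize(
        "cadd,expected",
        [(16.55, False), (33.0, True), (20.0, True), (19.999, False)],
    )
    def test_splice_cadd_threshold_inclusive_at_20(self, cadd, expected):
        record = make_record(
            consequence="splice",
            predictors=PredictorProfile(cadd_phred=cadd),
        )
        call = classify_variant(record)
        assert call.deleterious is expected
        assert call.rule_fired == ("lof_cadd" if expected else "none")

    def test_loftool_fallback_when_cadd_absent(self):
        record = make_record(
            consequence="frameshift",
            predictors=PredictorProfile(loftool_label="PD", loftool_score=0.514),
        )
        call = classify_variant(record)
        assert call.deleterious and call.rule_fired == "lof_tool"

    def test_lof_without_any_annotation_cannot_be_built(self):
        with pytest.raises(ValidationError):
            make_record(consequence="splice", predictors=PredictorProfile())

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        sift=st.sampled_from(["D", "T", None]),
        pp2=st.sampled_from(["PD", "B", None]),
        ma=st.sampled_from(["M", "H", "N", "L", None]),
        novel=st.booleans(),
        flip=st.sampled_from(["sift", "pp2", "ma"]),
    )
    def test_adding_an_abnormality_never_flips_deleterious_off(
        self, sift, pp2, ma, novel, flip
    ):
        profile = PredictorProfile(
            sift_label=sift, pp2_humdiv_label=pp2, ma_label=ma
        )
        if not (profile.has_sift or profile.has_pp2 or profile.has_ma):
            return
        record = make_record(
            dbsnp="New" if novel else "rs1",
            allele_freq=None if novel else 0.01,
            predictors=profile,
        )
        before = classify_variant(record)
        stronger = dataclasses.replace(
            profile,
            **{
                "sift": {"sift_label": "D"},
                "pp2": {"pp2_humdiv_label": "PD"},
                "ma": {"ma_label": "H"},
            }[flip],
        )
        after = classify_variant(dataclasses.replace(record, predictors=stronger))
        assert after.deleterious >= before.deleterious


class TestFilterVariants:
    def test_tga_panel_keeps_benign(self):
        record = make_record(panel="tga_associated", clinical_class="benign")
        assert filter_variants([record]) == [record]

    def test_cilia_panel_drops_benign_keeps_vus_and_pathogenic(self):
        benign = make_record(panel="motile", clinical_class="benign")
        vus = make_record(panel="motile", clinical_class="VUS", nt_change="c.2A>G")
        lp = make_record(
            panel="motile", clinical_class="likely_pathogenic", nt_change="c.3A>G"
        )
        assert filter_variants([benign, vus, lp]) == [vus, lp]

    def test_empty_input(self):
        assert filter_variants([]) == []

    def test_gene_outside_declared_panel_is_error(self):
        from ciliavar.models import GenePanel

        record = make_record(gene="NOTAGENE")
        panels = {"motile": GenePanel("motile", frozenset({"DNAH9"}))}
        with pytest.raises(ValidationError):
            filter_variants([record], panels)


class TestGeneGenotypeSummary:
    def _call(self, deleterious=True):
        from ciliavar.models import TriageCall

        return TriageCall(
            deleterious=deleterious,
            abnormal_predictors=frozenset({"SIFT", "PP2"}) if deleterious else frozenset(),
            rule_fired="missense_two_of_three" if deleterious else "none",
        )

    def test_two_deleterious_hets_are_compound(self):
        records = [
            make_record(patient_id="T180401", nt_change="c.3050A>G"),
            make_record(patient_id="T180401", nt_change="c.5151+1G>A",
                        consequence="splice",
                        predictors=PredictorProfile(cadd_phred=34.0)),
        ]
        calls = [self._call(), self._call()]
        summary = summarize_gene_genotype(records, calls)
        assert summary.compound_het and summary.n_deleterious_het == 2

    def test_single_deleterious_het_is_not_compound(self):
        summary = summarize_gene_genotype([make_record()], [self._call()])
        assert not summary.compound_het

    def test_one_non_deleterious_of_two_is_not_compound(self):
        records = [
            make_record(nt_change="c.1A>G"),
            make_record(nt_change="c.2A>G"),
        ]
        calls = [self._call(True), self._call(False)]
        assert not summarize_gene_genotype(records, calls).compound_het

    def test_same_change_twice_is_not_compound(self):
        records = [make_record(), make_record()]
        calls = [self._call(), self._call()]
        assert not summarize_gene_genotype(records, calls).compound_het

    def test_mixed_patients_rejected(self):
        records = [make_record(patient_id="P1"), make_record(patient_id="P2")]
        with pytest.raises(ValidationError):
            summarize_gene_genotype(records, [self._call(), self._call()])


COHORT_9M_2F = Cohort(
    patients=tuple(
        (f"P{i:02d}", "male" if i <= 9 else "female") for i in range(1, 12)
    )
)


class TestAlleleCount:
    def test_two_heterozygotes_give_2_of_22(self):
        records = [
            make_record(patient_id="P01"),
            make_record(patient_id="P02"),
        ]
        assert allele_count(records, COHORT_9M_2F) == (2, 22)

    def test_two_homs_plus_het_give_5_of_22(self):
        records = [
            make_record(patient_id="P01", zygosity="hom"),
            make_record(patient_id="P02", zygosity="hom"),
            make_record(patient_id="P03"),
        ]
        assert allele_count(records, COHORT_9M_2F) == (5, 22)

    def test_x_linked_hemizygote_gives_1_of_13(self):
        record = make_record(
            patient_id="P01", zygosity="hemi", chromosome_class="X", inheritance="XL"
        )
        assert allele_count([record], COHORT_9M_2F) == (1, 13)

    def test_duplicate_patient_rows_rejected(self):
        records = [make_record(patient_id="P01"), make_record(patient_id="P01")]
        with pytest.raises(ValidationError, match="duplicate"):
            allele_count(records, COHORT_9M_2F)

    def test_carrier_outside_cohort_rejected(self):
        with pytest.raises(ValidationError):
            allele_count([make_record(patient_id="NOPE")], COHORT_9M_2F)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.randoms(use_true_random=False))
    def test_order_invariance_and_k_le_n(self, rnd):
        patients = [f"P{i:02d}" for i in range(1, 12)]
        carriers = rnd.sample(patients, rnd.randint(1, 11))
        records = [
            make_record(patient_id=p, zygosity=rnd.choice(["het", "hom"]))
            for p in carriers
        ]
        k, n = allele_count(records, COHORT_9M_2F)
        shuffled = records[:]
        rnd.shuffle(shuffled)
        assert allele_count(shuffled, COHORT_9M_2F) == (k, n)
        assert 0 < k <= n
        if k == n:
            assert all(r.zygosity == "hom" for r in records) and len(records) == 11


class TestAnnotationConsistency:
    def test_female_hemizygote_is_surfaced(self, study_records, study_cohort):
        messages = annotation_consistency_report(study_records, study_cohort)
        assert any("T181001" in m and "OFD1" in m and "hemizygous" in m for m in messages)
        # the male OFD1 hemizygote is legitimate and must NOT be flagged
        assert not any("T180801" in m and "hemizygous" in m for m in messages)
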