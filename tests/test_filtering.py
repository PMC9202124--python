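"""Consensus somatic filter, germline filter, clonal-hematopoiesis flag, QC."""
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melscape.filtering import (
    CallerStatus,
    GermlineCallRecord,
    SomaticCallRecord,
    apply_somatic_evidence_filters,
    filter_germline_variant,
    filter_population_snps,
    flag_clonal_hematopoiesis,
    is_candidate_pathogenic_germline,
    merge_caller_calls,
    sample_qc_filter,
)
from melscape.genome import GeneModel

TSG = GeneModel("NF1", "chr17", 29_000_000, 29_080_000, "17q", role="tsg")
ONCO = GeneModel("KIT", "chr12", 100_000_000, 100_040_000, "12q", role="oncogene")


def somatic(
    both_pass=True,
    one_pass=False,
    t_depth=60,
    t_alt=20,
    n_depth=60,
    n_alt=0,
    region="coding",
    vclass="SNV",
    pop_af=0.0,
    artifact=False,
    filters1=(),
    pos=100,
):
    if one_pass:
        c1, c2 = CallerStatus(True, True, tuple(filters1)), CallerStatus(False, False)
    elif both_pass:
        c1, c2 = CallerStatus(True, True, tuple(filters1)), CallerStatus(True, True)
    else:
        c1, c2 = CallerStatus(True, False, tuple(filters1)), CallerStatus(True, False)
    return SomaticCallRecord(
        "s1", "chr1", pos, "C" if vclass == "SNV" else "C", "T" if vclass == "SNV" else "CTT",
        vclass, region, c1, c2, t_depth, t_alt, n_depth, n_alt,
        population_af={"gnomad": pop_af}, orientation_artifact=artifact,
    )


class TestMerge:
    def test_shared_variant_keeps_both_statuses(self):
        a = somatic(one_pass=True)
        b = somatic()
        merged = merge_caller_calls([a], [b])
        assert len(merged) == 1
        assert merged[0].caller1.passed and merged[0].caller2.passed

    def test_channel2_only_variant(self):
        b = somatic()
        b.caller1 = CallerStatus(False, False)
        merged = merge_caller_calls([], [b])
        assert len(merged) == 1 and not merged[0].caller1.called

    def test_union_count(self):
        shared = [somatic(pos=p) for p in (1, 2, 3)]
        only1 = [somatic(pos=p) for p in (10, 11)]
        only2 = [somatic(pos=p) for p in (20, 21)]
        merged = merge_caller_calls(shared + only1, shared + only2)
        assert len(merged) == 7

    def test_read_counts_from_channel1(self):
        a, b = somatic(t_alt=15), somatic(t_alt=25)
        assert merge_caller_calls([a], [b])[0].tumor_alt == 15

    def test_conflicting_ref_is_error(self):
        a = somatic()
        b = SomaticCallRecord("s1", "chr1", 100, "G", "T", "SNV", "coding")
        with pytest.raises(ValueError, match="conflicting ref"):
            merge_caller_calls([a], [b])


class TestPopulationSnps:
    @pytest.mark.parametrize(
        "af,kept", [(0.015, False), (0.009, True), (0.01, True), (0.0101, False)]
    )
    def test_strict_threshold(self, af, kept):
        out = filter_population_snps([somatic(pop_af=af)])
        assert bool(out) == kept

    def test_missing_database_counts_as_zero(self):
        rec = somatic()
        rec.population_af = {}
        assert filter_population_snps([rec])


class TestEvidenceRules:
    def test_both_pass_minimum_four_alt_reads(self):
        assert apply_somatic_evidence_filters(somatic(t_alt=4)).keep
        d = apply_somatic_evidence_filters(somatic(t_alt=3))
        assert not d.keep and "LOW_SUPPORT_BOTH_PASS" in d.reasons

    def test_single_tool_thresholds(self):
        rec = somatic(one_pass=True, t_depth=12, t_alt=6, n_depth=15, n_alt=1)
        assert apply_somatic_evidence_filters(rec).keep

    def test_single_tool_low_coverage(self):
        rec = somatic(one_pass=True, t_depth=9, t_alt=6, n_depth=15, n_alt=0)
        assert "SINGLE_TOOL_COVERAGE" in apply_somatic_evidence_filters(rec).reasons

    def test_single_tool_normal_contamination_or_rule(self):
        # 2/30 = 6.7% fails both arms; 2/100 = 2% passes the MAF arm
        bad = somatic(one_pass=True, t_alt=8, n_depth=30, n_alt=2)
        good = somatic(one_pass=True, t_alt=8, n_depth=100, n_alt=2)
        assert "SINGLE_TOOL_NORMAL_CONTAM" in apply_somatic_evidence_filters(bad).reasons
        assert apply_somatic_evidence_filters(good).keep

    def test_noncoding_requires_both_pass(self):
        assert apply_somatic_evidence_filters(somatic(region="noncoding")).keep
        d = apply_somatic_evidence_filters(somatic(one_pass=True, region="noncoding"))
        assert not d.keep and "NONCODING_NOT_BOTH_PASS" in d.reasons

    def test_orientation_artifact_snv_dropped(self):
        d = apply_somatic_evidence_filters(somatic(artifact=True))
        assert not d.keep and "ORIENTATION_ARTIFACT" in d.reasons

    @pytest.mark.parametrize("label", ["clustered_events", "clustered_events;haplotype"])
    def test_clustered_indels_dropped(self, label):
        d = apply_somatic_evidence_filters(somatic(vclass="INS", filters1=(label,)))
        assert not d.keep and "CLUSTERED_EVENTS" in d.reasons

    def test_clustered_label_must_match_exactly(self):
        d = apply_somatic_evidence_filters(somatic(vclass="INS", filters1=("clustered_events;x",)))
        assert d.keep

    def test_no_pass_anywhere_dropped(self):
        d = apply_somatic_evidence_filters(somatic(both_pass=False))
        assert not d.keep

    def test_idempotent_and_deterministic(self):
        rec = somatic(one_pass=True, t_alt=8, n_alt=1)
        assert apply_somatic_evidence_filters(rec) == apply_somatic_evidence_filters(rec)

    @settings(deadline=None, max_examples=100)
    @given(
        t_alt=st.integers(min_value=0, max_value=50),
        bump=st.integers(min_value=1, max_value=20),
        one_pass=st.booleans(),
        region=st.sampled_from(["coding", "noncoding"]),
    )
    def test_monotone_in_tumor_alt(self, t_alt, bump, one_pass, region):
        """Raising alt support never flips a kept variant to dropped."""
        low = somatic(one_pass=one_pass, t_depth=100, t_alt=t_alt, region=region)
        high = somatic(one_pass=one_pass, t_depth=100, t_alt=t_alt + bump, region=region)
        if apply_somatic_evidence_filters(low).keep:
            assert apply_somatic_evidence_filters(high).keep


def germline(alt_reads=20, depth=50, pop_af=0.0, clinvar="unknown", oncokb="unknown",
             dmg="nonsense", near_c=False, t_depth=None, t_alt=None):
    return GermlineCallRecord(
        "p1", "chr17", 29_050_000, "C", "T", depth, alt_reads,
        population_af={"gnomad": pop_af}, clinvar_label=clinvar, oncokb_label=oncokb,
        damaging_class=dmg, near_c_terminus=near_c, gene="NF1",
        tumor_depth_at_locus=t_depth, tumor_alt_at_locus=t_alt,
    )


class TestGermlineFilter:
    def test_boundaries_inclusive(self):
        assert filter_germline_variant(germline(alt_reads=4, depth=16)).keep

    def test_few_reads_dropped(self):
        assert not filter_germline_variant(germline(alt_reads=3, depth=6)).keep

    def test_low_af_dropped(self):
        assert not filter_germline_variant(germline(alt_reads=10, depth=50)).keep

    def test_common_snp_dropped(self):
        assert not filter_germline_variant(germline(pop_af=0.02)).keep

    def test_zero_depth_is_error(self):
        with pytest.raises(ValueError):
            filter_germline_variant(germline(alt_reads=0, depth=0))

    def test_candidate_pathogenic_tsg_frameshift(self):
        assert is_candidate_pathogenic_germline(germline(dmg="frameshift"), TSG)

    def test_near_c_terminus_excluded(self):
        assert not is_candidate_pathogenic_germline(germline(near_c=True), TSG)

    @pytest.mark.parametrize(
        "clinvar,oncokb", [("benign_likely_benign", "unknown"), ("unknown", "neutral"),
                           ("unknown", "inconclusive")]
    )
    def test_benign_annotations_excluded(self, clinvar, oncokb):
        assert not is_candidate_pathogenic_germline(germline(clinvar=clinvar, oncokb=oncokb), TSG)

    def test_oncogene_missense_needs_annotation(self):
        assert not is_candidate_pathogenic_germline(germline(dmg="missense"), ONCO)
        assert is_candidate_pathogenic_germline(germline(dmg="missense", oncokb="oncogenic"), ONCO)


class TestClonalHematopoiesis:
    def test_blood_only_variant_flagged(self):
        assert flag_clonal_hematopoiesis(germline(t_depth=62, t_alt=0), tumor_minor_cn=1)

    def test_present_in_tumor_not_flagged(self):
        assert not flag_clonal_hematopoiesis(germline(t_depth=60, t_alt=20), tumor_minor_cn=1)

    def test_loh_explains_absence(self):
        assert not flag_clonal_hematopoiesis(germline(t_depth=62, t_alt=0), tumor_minor_cn=0)

    def test_shallow_tumor_not_flagged(self):
        assert not flag_clonal_hematopoiesis(germline(t_depth=10, t_alt=0), tumor_minor_cn=1)


class TestSampleQC:
    def sheet(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "patient_id", "specimen", "mean_coverage", "purity"]
        )

    def test_coverage_and_purity_floors(self):
        s = self.sheet(
            [
                ("a", "p1", "primary", 24.9, 0.5),
                ("b", "p2", "primary", 25.0, 0.5),
                ("c", "p3", "primary", 80.0, 0.19),
                ("d", "p4", "primary", 80.0, 0.20),
            ]
        )
        assert sample_qc_filter(s) == ["b", "d"]

    def test_highest_purity_metastasis_kept(self):
        s = self.sheet(
            [
                ("m1", "p1", "metastasis", 80, 0.4),
                ("m2", "p1", "metastasis", 80, 0.6),
                ("pr", "p1", "primary", 80, 0.9),
            ]
        )
        assert sample_qc_filter(s) == ["m2"]

    def test_no_metastasis_falls_back_to_highest_purity(self):
        s = self.sheet([("a", "p1", "primary", 80, 0.4), ("b", "p1", "primary", 80, 0.7)])
        assert sample_qc_filter(s) == ["b"]


class TestFilterRecoversTruth:
    def test_noiseless_channels_keep_exactly_true_set(self, clean_cohort):
        """With FP=FN=0 and generous depth the filter output equals the truth."""
        from melscape import io as msio
        from melscape.filtering import apply_somatic_evidence_filters

        cfg, bundle, truth = clean_cohort
        records = msio.somatic_records_from_frame(bundle.mutations)
        kept = {
            r.key
            for r in records
            if r.max_population_af <= 0.01 and apply_somatic_evidence_filters(r).keep
        }
        true_keys = {
            (r["sample"], r["chrom"], int(r["pos"]), r["ref"], r["alt"])
            for r in truth.true_mutations.to_dict("records")
        }
        assert kept == true_keys
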