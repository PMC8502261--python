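"""Classification criteria, CNVR clustering, aneuploidy detection."""
import random

import pytest

import cnvcohort as cc
from cnvcohort import GenomicInterval
from cnvcohort.classify import NON_CAUSATIVE, POTENTIALLY_CAUSATIVE


def popdb(*records):
    return cc.ReferenceDb("population", tuple(
        cc.DbRecord(GenomicInterval(c, s, e), t, frequency=f)
        for c, s, e, t, f in records))


def call(chrom, start, end, ctype="DUP", sample="S1", markers=100):
    return cc.CnvCall(sample, GenomicInterval(chrom, start, end), ctype,
                      markers)


class TestCausative:
    def test_coverage_exactly_070_is_non_causative(self):
        """The >= 70% boundary is inclusive."""
        c = call("1", 0, 1000)
        db = popdb(("1", 0, 700, "DUP", 0.1))
        status, cov = cc.classify_causative(c, db)
        assert cov == pytest.approx(0.70)
        assert status == NON_CAUSATIVE

    def test_coverage_069_is_potentially_causative(self):
        c = call("1", 0, 1000)
        status, cov = cc.classify_causative(
            c, popdb(("1", 0, 690, "DUP", 0.1)))
        assert cov == pytest.approx(0.69)
        assert status == POTENTIALLY_CAUSATIVE

    def test_no_hits(self):
        status, cov = cc.classify_causative(call("1", 0, 1000), popdb())
        assert (status, cov) == (POTENTIALLY_CAUSATIVE, 0.0)

    def test_fully_contained_in_one_record(self):
        status, cov = cc.classify_causative(
            call("1", 100, 200), popdb(("1", 0, 1000, "DUP", 0.1)))
        assert (status, cov) == (NON_CAUSATIVE, 1.0)

    def test_type_matching_toggle(self):
        c = call("1", 0, 1000, "DUP")
        db = popdb(("1", 0, 1000, "DEL", 0.1))
        assert cc.classify_causative(c, db)[0] == POTENTIALLY_CAUSATIVE
        assert cc.classify_causative(c, db, type_matched=False)[0] \
            == NON_CAUSATIVE

    def test_monotone_in_database_records(self):
        """Adding records can only move a call toward non-causative."""
        c = call("1", 0, 1000)
        recs = [("1", i * 100, i * 100 + 100, "DUP", 0.1) for i in range(10)]
        prev = 0.0
        for k in range(len(recs) + 1):
            _, cov = cc.classify_causative(c, popdb(*recs[:k]))
            assert cov >= prev
            prev = cov


class TestClustering:
    def test_chr21_duplications_form_one_cnvr(self, cavc_calls):
        chr21 = [c for c in cavc_calls if c.interval.chrom == "21"]
        assert len(chr21) == 39
        (cnvr,) = cc.cluster_cnvrs(chr21)
        assert len(cnvr.carriers) == 39
        assert cnvr.interval == GenomicInterval("21", 13038108, 46687133)

    def test_full_cavc_table_yields_nine_cnvrs(self, cavc_calls):
        assert len(cc.cluster_cnvrs(cavc_calls)) == 9

    def test_disjoint_calls_stay_separate(self):
        a, b = call("1", 0, 1000, sample="A"), call("1", 5000, 6000,
                                                    sample="B")
        assert len(cc.cluster_cnvrs([a, b])) == 2

    def test_different_types_never_merge(self):
        a = call("1", 0, 1000, "DUP")
        b = call("1", 0, 1000, "DEL")
        assert len(cc.cluster_cnvrs([a, b])) == 2

    def test_partition_and_permutation_invariance(self, bundled):
        calls = list(bundled["calls"])
        reference = cc.cluster_cnvrs(calls)
        # partition: every call in exactly one CNVR
        assert sum(len(r.calls) for r in reference) == len(calls)
        ref_ids = [(r.region_id, r.carriers) for r in reference]
        rng = random.Random(7)
        for _ in range(5):
            rng.shuffle(calls)
            got = cc.cluster_cnvrs(calls)
            assert [(r.region_id, r.carriers) for r in got] == ref_ids

    def test_single_linkage_chains_through_intermediate(self):
        # a-b and b-c overlap reciprocally >= 0.5 but a-c do not
        a = call("1", 0, 1000, sample="A")
        b = call("1", 400, 1400, sample="B")
        c = call("1", 800, 1800, sample="C")
        assert cc.reciprocal_overlap(a.interval, c.interval) < 0.5
        (cnvr,) = cc.cluster_cnvrs([a, b, c])
        assert cnvr.carriers == {"A", "B", "C"}


class TestFrequencies:
    @pytest.mark.parametrize("k,n,expected", [
        (39, 262, 14.8855), (1, 262, 0.3817), (0, 262, 0.0),
    ])
    def test_cohort_frequency_table_mode(self, k, n, expected):
        carriers = frozenset(f"S{i}" for i in range(k)) or frozenset()
        cnvr = cc.CnvRegion("r", GenomicInterval("1", 0, 1000), "DUP", (),
                            carriers)
        assert cc.cohort_frequency(cnvr, n) == expected

    def test_cohort_frequency_text_mode(self):
        cnvr = cc.CnvRegion("r", GenomicInterval("1", 0, 1000), "DUP", (),
                            frozenset(f"S{i}" for i in range(39)))
        assert cc.cohort_frequency(cnvr, 262, ndigits=2) == 14.89

    def test_zero_cohort_rejected(self):
        cnvr = cc.CnvRegion("r", GenomicInterval("1", 0, 1000), "DUP", (),
                            frozenset())
        with pytest.raises(ValueError):
            cc.cohort_frequency(cnvr, 0)

    @pytest.mark.parametrize("freq,expected", [
        (0.3817, "rare"), (14.8855, "common"), (1.0, "common"),
        (0.9999, "rare"),
    ])
    def test_rarity_boundary(self, freq, expected):
        assert cc.classify_rarity(freq) == expected


class TestNovelty:
    clin = cc.ReferenceDb("clinical", (
        cc.DbRecord(GenomicInterval("1", 0, 500), "DUP", n_records=10),),
        n_total_records=1000)

    def test_absent_from_both_dbs_is_novel(self):
        assert cc.flag_novel(call("2", 0, 1000), popdb(), self.clin)

    def test_high_population_coverage_not_novel(self):
        db = popdb(("1", 0, 950, "DUP", 0.1))
        assert not cc.flag_novel(call("1", 0, 1000), db, self.clin)

    def test_clinical_only_coverage_not_novel(self):
        # 5% population coverage but 50% clinical coverage
        db = popdb(("1", 950, 1000, "DUP", 0.1))
        assert not cc.flag_novel(call("1", 0, 1000), db, self.clin)


class TestAneuploidy:
    def test_whole_21q_duplication_flags_gain(self, toy_build):
        c = cc.CnvCall("S1", cc.from_table_coords("21", 13038109, 46687133),
                       "DUP", 3449)
        (flag,) = cc.detect_chromosome_level_events([c], toy_build)
        assert flag.direction == "gain"
        assert flag.covered_fraction == pytest.approx(0.9985, abs=1e-3)

    def test_small_duplication_no_flag(self, toy_build):
        c = call("21", 20_000_000, 20_500_000)
        c = cc.CnvCall("S1", c.interval, "DUP", 100)
        assert cc.detect_chromosome_level_events([c], toy_build) == []

    def test_full_span_deletion_flags_loss(self, toy_build):
        c = cc.CnvCall("S1", GenomicInterval("21", 13_000_000, 46_700_000),
                       "DEL", 3000)
        (flag,) = cc.detect_chromosome_level_events([c], toy_build)
        assert flag.direction == "loss"
        assert flag.covered_fraction == 1.0

    def test_split_calls_union_before_thresholding(self, toy_build):
        parts = [cc.CnvCall("S1", GenomicInterval("21", 13_000_000,
                                                  30_000_000), "DUP", 100),
                 cc.CnvCall("S1", GenomicInterval("21", 29_000_000,
                                                  46_700_000), "DUP", 100)]
        (flag,) = cc.detect_chromosome_level_events(parts, toy_build)
        assert flag.covered_fraction == 1.0

    def test_unknown_chromosome_errors(self, toy_build):
        c = call("99", 0, 1000)
        with pytest.raises(cc.UnknownContigError):
            cc.detect_chromosome_level_events([c], toy_build)

    def test_bundled_cohort_has_39_trisomy_flags(self, bundled_result):
        flags = bundled_result.aneuploidy_flags
        gains21 = [f for f in flags
                   if f.chrom == "21" and f.direction == "gain"]
        assert len(gains21) == 39 and len(flags) == 39


class TestEndToEndLabels:
    def test_printed_classification_reproduced(self, bundled,
                                               bundled_result):
        """With the classification column hidden, population-db coverage
        alone must reproduce the printed label for all 65 rows."""
        printed = {}
        for c in bundled["calls"]:
            printed[(c.sample_id, c.interval, c.cnv_type)] = \
                c.info["cnv_class"]
        assert len(bundled_result.classified) == 65
        for cl in bundled_result.classified:
            want = printed[(cl.sample_id, cl.interval, cl.cnv_type)]
            got = ("N-causative" if cl.causative_status == NON_CAUSATIVE
                   else "P-causative")
            assert got == want, cl.sample_id
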