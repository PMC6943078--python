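"""Anchor-gene detection, haplotype splitting and exclusivity evidence."""

import pytest

import allelekit as ak
from conftest import TOY_V1, TOY_V2, make_read


class TestAlleleUsageByGene:
    def test_single_allele(self):
        reads = [make_read(read_id=f"r{i}", j_call="IGHJ6*02") for i in range(5)]
        assert ak.allele_usage_by_gene(reads, "J") == {"IGHJ6": {"IGHJ6*02": 5}}

    def test_heterozygous_gene_splits_evenly(self):
        reads = [
            make_read(read_id=f"r{i}", j_call="IGHJ6*02" if i % 2 else "IGHJ6*03")
            for i in range(100)
        ]
        usage = ak.allele_usage_by_gene(reads, "J")
        assert usage["IGHJ6"] == {"IGHJ6*02": 50, "IGHJ6*03": 50}

    def test_empty_input(self):
        assert ak.allele_usage_by_gene([], "J") == {}

    def test_ambiguous_calls_excluded(self):
        reads = [make_read(j_call="IGHJ6*02,IGHJ6*03")]
        assert ak.allele_usage_by_gene(reads, "J") == {}

    def test_restriction_to_unmutated_studied_segment(self, toy_refset):
        mutated = TOY_V1[:-1] + ("A" if TOY_V1[-1] != "A" else "C")
        reads = [
            make_read(read_id="r1", alignment=TOY_V1, j_call="TSTJ1*01"),
            make_read(read_id="r2", alignment=mutated, j_call="TSTJ1*01"),
        ]
        usage = ak.allele_usage_by_gene(reads, "J", refset=toy_refset, studied_segment="V")
        assert usage == {"TSTJ1": {"TSTJ1*01": 1}}


class TestDetectAnchor:
    def test_balanced_heterozygote_qualifies(self):
        usage = {"IGHJ6": {"IGHJ6*02": 520, "IGHJ6*03": 480}}
        (cand,) = ak.detect_anchor(usage)
        assert cand.gene == "IGHJ6"
        assert set(cand.alleles) == {"IGHJ6*02", "IGHJ6*03"}

    def test_unbalanced_below_minor_fraction_does_not_qualify(self):
        usage = {"IGHJ6": {"IGHJ6*02": 950, "IGHJ6*03": 50}}
        assert ak.detect_anchor(usage, min_minor_fraction=0.2) == []

    def test_three_way_split_does_not_qualify(self):
        usage = {"IGHJ6": {"IGHJ6*01": 34, "IGHJ6*02": 33, "IGHJ6*03": 33}}
        assert ak.detect_anchor(usage, min_total=50) == []

    def test_low_total_does_not_qualify(self):
        usage = {"IGHJ6": {"IGHJ6*02": 30, "IGHJ6*03": 30}}
        assert ak.detect_anchor(usage, min_total=100) == []

    def test_candidates_sorted_by_total(self):
        usage = {
            "IGHJ4": {"IGHJ4*02": 100, "IGHJ4*03": 100},
            "IGHJ6": {"IGHJ6*02": 300, "IGHJ6*03": 300},
        }
        cands = ak.detect_anchor(usage)
        assert [c.gene for c in cands] == ["IGHJ6", "IGHJ4"]


class TestExclusivityScore:
    @pytest.mark.parametrize(
        "c1,c2,min_reads,expected",
        [
            (25, 0, 10, (True, 0.0)),
            (25, 1, 10, (False, 0.04)),
            (0, 0, 10, (False, 0.0)),
            (5, 0, 10, (False, 0.0)),  # too few reads for evidence
            (0, 12, 10, (True, 0.0)),  # symmetric in the anchors
        ],
    )
    def test_rule(self, c1, c2, min_reads, expected):
        flag, ratio = ak.exclusivity_score(c1, c2, min_reads)
        assert flag == expected[0] and ratio == pytest.approx(expected[1])


class TestHaplotypeCounts:
    def _reads(self):
        reads = []
        # allele *01 on both haplotypes, *02 only with TSTJ1*02
        for i in range(12):
            reads.append(make_read(read_id=f"a{i}", v_call="TSTV1-1*01",
                                   j_call="TSTJ1*01" if i % 2 else "TSTJ1*02"))
        for i in range(15):
            reads.append(make_read(read_id=f"b{i}", v_call="TSTV1-1*02",
                                   j_call="TSTJ1*02", alignment=TOY_V2))
        return reads

    def test_exclusive_allele_flagged(self):
        rep = ak.haplotype_counts(self._reads(), "TSTJ1", ("TSTJ1*01", "TSTJ1*02"), "V")
        assert rep.counts("TSTV1-1*02") == (0, 15)
        assert rep.exclusivity["TSTV1-1*02"] == (True, 0.0)

    def test_shared_allele_not_flagged(self):
        rep = ak.haplotype_counts(self._reads(), "TSTJ1", ("TSTJ1*01", "TSTJ1*02"), "V")
        c1, c2 = rep.counts("TSTV1-1*01")
        assert c1 > 0 and c2 > 0
        assert rep.exclusivity["TSTV1-1*01"][0] is False

    def test_column_sums_conserve_anchor_read_counts(self):
        reads = self._reads()
        rep = ak.haplotype_counts(reads, "TSTJ1", ("TSTJ1*01", "TSTJ1*02"), "V")
        sums = [0, 0]
        for alleles in rep.per_gene_counts.values():
            for c1, c2 in alleles.values():
                sums[0] += c1
                sums[1] += c2
        expected = [
            sum(1 for r in reads if r.j_call == "TSTJ1*01"),
            sum(1 for r in reads if r.j_call == "TSTJ1*02"),
        ]
        assert sums == expected

    def test_other_anchor_gene_alleles_excluded_from_split(self):
        reads = self._reads() + [
            make_read(read_id="x1", v_call="TSTV1-1*01", j_call="TSTJ1*03")
        ]
        rep = ak.haplotype_counts(reads, "TSTJ1", ("TSTJ1*01", "TSTJ1*02"), "V")
        assert sum(rep.counts("TSTV1-1*01")) == 12

    def test_missing_anchor_alleles_is_an_error(self):
        with pytest.raises(ValueError, match="anchor"):
            ak.haplotype_counts(self._reads(), "TSTJ9", ("TSTJ9*01", "TSTJ9*02"), "V")


class TestOnSimulatedData:
    def test_linked_novel_allele_is_exclusive(self, sim):
        pr = ak.filter_productive(sim.reads)
        usage = ak.allele_usage_by_gene(pr, "J", refset=sim.refset, studied_segment="V")
        (anchor,) = ak.detect_anchor(usage)
        assert anchor.gene == sim.config.anchor_gene
        rep = ak.haplotype_counts(pr, anchor.gene, anchor.alleles, "V", sim.refset)
        flag, ratio = rep.exclusivity["IGHV_S1"]
        assert flag and ratio == 0.0
        # the split matches the generator's cross-tabulation
        a1, a2 = anchor.alleles
        assert rep.counts("IGHV_S1") == (
            sim.truth.cross_tab["IGHV_S1"][a1],
            sim.truth.cross_tab["IGHV_S1"][a2],
        )

    def test_reference_alleles_are_not_exclusive(self, sim):
        pr = ak.filter_productive(sim.reads)
        usage = ak.allele_usage_by_gene(pr, "J", refset=sim.refset, studied_segment="V")
        (anchor,) = ak.detect_anchor(usage)
        rep = ak.haplotype_counts(pr, anchor.gene, anchor.alleles, "V", sim.refset)
        for allele, (flag, _) in rep.exclusivity.items():
            if allele != "IGHV_S1":
                assert not flag

    def test_homozygous_subject_yields_no_anchor(self, sim_homozygous):
        pr = ak.filter_productive(sim_homozygous.reads)
        usage = ak.allele_usage_by_gene(
            pr, "J", refset=sim_homozygous.refset, studied_segment="V"
        )
        assert ak.detect_anchor(usage) == []
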