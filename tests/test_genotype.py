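"""Standardized genotype report: exact-match logic, word-formulas, CSV format."""

import csv

import pytest

import allelekit as ak
from allelekit.genotype import EmptyRepertoireError, GENOTYPE_COLUMNS
from conftest import TOY_V1, TOY_V2, make_read


class TestIsUnmutated:
    def test_full_length_germline_read_matches(self, toy_refset):
        read = make_read(alignment=TOY_V1)
        assert ak.is_unmutated(read, toy_refset["TSTV1-1*01"])

    def test_single_substitution_is_mutated(self, toy_refset):
        mutated = TOY_V1[:-1] + ("A" if TOY_V1[-1] != "A" else "C")
        assert not ak.is_unmutated(make_read(alignment=mutated), toy_refset["TSTV1-1*01"])

    def test_three_prime_truncation_still_matches(self, toy_refset):
        # oracle: only covered positions are compared, trimmed tail ignored
        read = make_read(alignment=TOY_V1[:-3])
        assert ak.is_unmutated(read, toy_refset["TSTV1-1*01"])

    def test_n_counts_as_mismatch(self, toy_refset):
        read = make_read(alignment="N" + TOY_V1[1:])
        assert not ak.is_unmutated(read, toy_refset["TSTV1-1*01"])

    def test_v_region_delimited_by_v_germline_end(self, toy_refset):
        # junction bases appended beyond the V region must not be compared
        read = make_read(alignment=TOY_V1 + "TTTTTT", v_germline_end=len(TOY_V1))
        assert ak.is_unmutated(read, toy_refset["TSTV1-1*01"])


def _reads_40_of_100_exact():
    reads = []
    mutated = TOY_V1[:-1] + ("A" if TOY_V1[-1] != "A" else "C")
    for i in range(100):
        reads.append(
            make_read(
                read_id=f"r{i}",
                alignment=TOY_V1 if i < 40 else mutated,
                junction_aa=f"CAR{i}W",
            )
        )
    return reads


class TestComputeGenotype:
    def test_assigned_unmutated_frequency_formula(self, toy_refset):
        gt = ak.compute_genotype(_reads_40_of_100_exact(), toy_refset, "V")
        row = gt.row("TSTV1-1*01")
        assert row.sequences == 100
        assert row.unmutated_sequences == 40
        assert row.assigned_unmutated_frequency == pytest.approx(40.0)

    def test_allelic_percentage_splits_within_gene(self, toy_refset):
        reads = [
            make_read(read_id=f"a{i}", v_call="TSTV1-1*01", alignment=TOY_V1)
            for i in range(30)
        ] + [
            make_read(read_id=f"b{i}", v_call="TSTV1-1*02", alignment=TOY_V2)
            for i in range(10)
        ]
        gt = ak.compute_genotype(reads, toy_refset, "V")
        assert gt.row("TSTV1-1*01").allelic_percentage == pytest.approx(75.0)
        assert gt.row("TSTV1-1*02").allelic_percentage == pytest.approx(25.0)

    def test_single_allele_all_unmutated_degenerate(self, toy_refset):
        reads = [make_read(read_id=f"r{i}") for i in range(5)]
        gt = ak.compute_genotype(reads, toy_refset, "V")
        row = gt.rows[0]
        assert row.allelic_percentage == pytest.approx(100.0)
        assert row.unmutated_frequency == pytest.approx(100.0)

    def test_empty_repertoire_is_an_error(self, toy_refset):
        with pytest.raises(EmptyRepertoireError):
            ak.compute_genotype([], toy_refset, "V")
        with pytest.raises(EmptyRepertoireError):
            ak.compute_genotype(
                [make_read(productive=False)], toy_refset, "V"
            )

    def test_ambiguous_calls_count_assigned_but_not_unmutated(self, toy_refset):
        reads = [make_read(read_id="r1", alignment=TOY_V1)] + [
            make_read(
                read_id=f"r{i}",
                v_call="TSTV1-1*01,TSTV1-1*02",
                alignment=TOY_V1,
            )
            for i in range(2, 5)
        ]
        row = ak.compute_genotype(reads, toy_refset, "V").row("TSTV1-1*01")
        assert row.sequences == 4 and row.unmutated_sequences == 1

    def test_unknown_allele_gets_row_with_empty_diff_fields(self, toy_refset):
        reads = [make_read(read_id="r1"), make_read(read_id="r2", v_call="TSTV9-9*01")]
        gt = ak.compute_genotype(reads, toy_refset, "V")
        assert gt.unknown_alleles == ["TSTV9-9*01"]
        row = gt.row("TSTV9-9*01")
        assert row.sequences == 1 and row.diff.closest_reference == ""

    def test_unique_counts_and_umis(self, toy_refset):
        reads = [
            make_read(read_id="r1", j_call="TSTJ1*01", umi="AAA", junction_aa="CAAW"),
            make_read(read_id="r2", j_call="TSTJ1*02", umi="AAA", junction_aa="CAAW"),
            make_read(read_id="r3", j_call="TSTJ1*02", umi="CCC", junction_aa="CCCW"),
        ]
        row = ak.compute_genotype(reads, toy_refset, "V").row("TSTV1-1*01")
        assert row.unique_js == 2 and row.unique_cdr3s == 2
        assert row.unmutated_umis == 2  # AAA shared by a duplicate pair


class TestGenotypeCsv:
    def test_header_is_the_standard_field_order(self, toy_refset, tmp_path):
        gt = ak.compute_genotype([make_read()], toy_refset, "V")
        out = tmp_path / "genotype.csv"
        ak.write_genotype_csv(gt, out)
        header = out.read_text().splitlines()[0]
        assert header == ",".join(GENOTYPE_COLUMNS)

    def test_two_rows_make_three_lines(self, toy_refset, tmp_path):
        reads = [
            make_read(read_id="r1", v_call="TSTV1-1*01", alignment=TOY_V1),
            make_read(read_id="r2", v_call="TSTV1-1*02", alignment=TOY_V2),
        ]
        out = tmp_path / "genotype.csv"
        ak.write_genotype_csv(ak.compute_genotype(reads, toy_refset, "V"), out)
        assert len(out.read_text().splitlines()) == 3

    def test_no_umi_data_leaves_cell_empty(self, toy_refset, tmp_path):
        out = tmp_path / "genotype.csv"
        ak.write_genotype_csv(
            ak.compute_genotype([make_read()], toy_refset, "V"), out
        )
        with open(out) as fh:
            rec = next(csv.DictReader(fh))
        assert rec["unmutated_umis"] == ""
        assert rec["nt_diff"] == ""  # reference allele: diff fields empty too

    def test_round_trip_preserves_values(self, toy_refset, tmp_path):
        gt = ak.compute_genotype(_reads_40_of_100_exact(), toy_refset, "V")
        out = tmp_path / "genotype.csv"
        ak.write_genotype_csv(gt, out)
        with open(out) as fh:
            rec = next(csv.DictReader(fh))
        assert rec["sequence_id"] == "TSTV1-1*01"
        assert rec["sequences"] == "100"
        assert rec["assigned_unmutated_frequency"] == "40.00"
        assert rec["unique_cdr3s"] == "100"


class TestNormalizationInvariants:
    def test_allelic_percentage_sums_to_100_per_gene(self, sim):
        by_gene = {}
        for row in sim.genotype.rows:
            if row.allelic_percentage is not None:
                gene = row.sequence_id.split("*")[0]
                by_gene.setdefault(gene, []).append(row.allelic_percentage)
        assert by_gene
        for gene, vals in by_gene.items():
            assert sum(vals) == pytest.approx(100.0, abs=0.01)

    def test_unmutated_frequency_sums_to_100(self, sim):
        total = sum(
            r.unmutated_frequency
            for r in sim.genotype.rows
            if r.unmutated_frequency is not None
        )
        assert total == pytest.approx(100.0, abs=0.01)

    def test_unmutated_never_exceeds_sequences(self, sim):
        for row in sim.genotype.rows:
            assert 0 <= row.unmutated_sequences <= row.sequences
            assert row.unique_cdr3s_unmutated <= row.unique_cdr3s
            assert row.unique_js_unmutated <= row.unique_js


def test_counts_recover_simulation_ground_truth(sim):
    """Every count field equals the generator's per-allele tally exactly."""
    for name, tally in sim.truth.tallies.items():
        row = sim.genotype.row(name)
        got = {
            "sequences": row.sequences,
            "unmutated_sequences": row.unmutated_sequences,
            "unmutated_umis": row.unmutated_umis,
            "unique_vs": row.unique_vs,
            "unique_ds": row.unique_ds,
            "unique_js": row.unique_js,
            "unique_cdr3s": row.unique_cdr3s,
            "unique_vs_unmutated": row.unique_vs_unmutated,
            "unique_ds_unmutated": row.unique_ds_unmutated,
            "unique_js_unmutated": row.unique_js_unmutated,
            "unique_cdr3s_unmutated": row.unique_cdr3s_unmutated,
        }
        assert {k: got[k] for k in tally} == tally, name
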