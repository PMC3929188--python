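"""Weighted counting, RPKM arithmetic, expression calls and binning."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oryzadiff import CountTable, call_expressed, emit_sam_fixture, log2_histogram, rpb, rpkm, weighted_gene_counts
from oryzadiff.quantification import (
    AlignmentRecord,
    assign_level_bins,
    bin_expression_levels,
    expression_profile,
    iter_sam,
)


def _rec(read_id, chrom, start_1based, span, nh=1, mapped=True):
    if not mapped:
        return AlignmentRecord(read_id, None, -1, -1, 1, False)
    return AlignmentRecord(read_id, chrom, start_1based - 1, start_1based - 1 + span, nh, True)


class TestRpkm:
    def test_worked_example(self):
        # 250 reads on a 2 kb gene out of 25 M mapped: 250 / (2 * 25) = 5
        assert rpkm(250, 2000, 25_000_000) == pytest.approx(5.0)

    def test_unit_case_and_zero(self):
        assert rpkm(1, 1000, 1_000_000) == pytest.approx(1.0)
        assert rpkm(0, 1234, 5_000_000) == 0.0

    def test_rpb(self):
        assert rpb(1, 1_000_000_000) == pytest.approx(1.0)

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            rpkm(10, 1000, 0)

    @given(
        st.floats(0, 1e6),
        st.integers(1, 100_000),
        st.floats(1e3, 1e9),
        st.floats(0.01, 100),
    )
    def test_scale_invariance(self, count, length, total, factor):
        # multiplying every count and the total by one factor leaves RPKM fixed
        a = rpkm(count, length, total)
        b = rpkm(count * factor, length, total * factor)
        assert a == pytest.approx(b, rel=1e-9)


class TestExpressedCall:
    def test_threshold_is_strict(self):
        vals = pd.Series({"a": 1.0, "b": 1.01, "c": 0.0})
        out = call_expressed(vals, 1.0)
        assert not out["a"] and out["b"] and not out["c"]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_expressed(pd.Series([1.0]), 0.0)


class TestLevelBins:
    def test_one_gene_per_bin(self):
        vals = pd.Series({"a": 0.5, "b": 5.0, "c": 50.0, "d": 500.0, "e": 5000.0})
        bins = assign_level_bins(vals, 1.0)
        assert list(bins) == ["not_detected", "low", "modest", "high", "extreme"]

    def test_boundaries_are_left_closed(self):
        vals = pd.Series({"x": 10.0, "y": 100.0, "z": 1000.0})
        assert list(assign_level_bins(vals, 1.0)) == ["modest", "high", "extreme"]

    def test_all_zero_profile(self):
        vals = pd.Series({"a": 0.0, "b": 0.0})
        assert set(assign_level_bins(vals, 1.0)) == {"not_detected"}

    def test_bins_partition_the_gene_set(self, small_study):
        profile = expression_profile(small_study.counts_25, small_study.genes)
        counts = bin_expression_levels(profile)
        assert counts.sum() == len(small_study.genes)
        assert counts["not_detected"] == (~profile["expressed"]).sum()


class TestLog2Histogram:
    def test_single_gene(self):
        edges, freq = log2_histogram(pd.Series([8.0]), bin_width=1.0)
        assert freq.sum() == 1
        i = int(freq.argmax())
        assert edges[i] <= 3.0 < edges[i + 1]

    def test_two_genes_adjacent_bins(self):
        edges, freq = log2_histogram(pd.Series([1.0, 2.0]), bin_width=1.0)
        assert list(freq) == [1, 1]
        assert edges[0] == 0.0 and edges[1] == 1.0

    def test_zero_rpkm_excluded_and_empty(self):
        edges, freq = log2_histogram(pd.Series([0.0, 0.0]))
        assert len(freq) == 0

    def test_frequencies_sum_to_included_genes(self, small_study):
        profile = expression_profile(small_study.counts_25, small_study.genes)
        _, freq = log2_histogram(profile["rpkm"])
        assert freq.sum() == (profile["rpkm"] > 0).sum()


class TestWeightedCounts:
    def test_empty_stream(self, toy_genes):
        table = weighted_gene_counts([], toy_genes)
        assert table.total_mapped_reads == 0.0
        assert (table.counts == 0).all()

    def test_multimapper_splits_weight(self, toy_genes):
        recs = [
            _rec("r1", "Chr1", 1100, 90, nh=2),  # inside gA
            _rec("r1", "Chr1", 3100, 90, nh=2),  # inside gB
        ]
        table = weighted_gene_counts(recs, toy_genes)
        assert table.counts["gA"] == pytest.approx(0.5)
        assert table.counts["gB"] == pytest.approx(0.5)
        assert table.total_mapped_reads == pytest.approx(1.0)

    def test_intergenic_read_counts_toward_total_only(self, toy_genes):
        recs = [_rec(f"r{i}", "Chr1", 1100 + i, 90) for i in range(3)]
        recs.append(_rec("r9", "Chr1", 2500, 90))  # between gA and gB
        table = weighted_gene_counts(recs, toy_genes)
        assert table.counts["gA"] == pytest.approx(3.0)
        assert table.counts.sum() == pytest.approx(3.0)
        assert table.total_mapped_reads == pytest.approx(4.0)

    def test_ambiguous_overlap_discarded_but_counted_in_total(self, overlapping_genes):
        # read spans the overlap of ovA (ends 2000) and ovB (starts 1801)
        recs = [_rec("r1", "Chr1", 1850, 90)]
        table = weighted_gene_counts(recs, overlapping_genes)
        assert table.counts.sum() == 0.0
        assert table.total_mapped_reads == pytest.approx(1.0)

    def test_unmapped_records_contribute_nothing(self, toy_genes):
        recs = [_rec("r1", None, 0, 0, mapped=False)]
        table = weighted_gene_counts(recs, toy_genes)
        assert table.total_mapped_reads == 0.0

    def test_mass_conservation(self, toy_genes):
        # weight assigned to genes can never exceed the mapped-read total;
        # equality holds when every alignment overlaps exactly one gene
        recs = [
            _rec("a", "Chr1", 1200, 90),
            _rec("b", "Chr2", 1100, 90),
            _rec("c", "Chr1", 5100, 90, nh=3),
        ]
        table = weighted_gene_counts(recs, toy_genes)
        assert table.counts.sum() == pytest.approx(table.total_mapped_reads)
        recs.append(_rec("d", "Chr1", 2500, 90))  # intergenic breaks equality
        table2 = weighted_gene_counts(recs, toy_genes)
        assert table2.counts.sum() < table2.total_mapped_reads


class TestSamReading:
    def test_fixture_matches_enumeration_oracle(self, tmp_path, small_study):
        sam_text, expected = emit_sam_fixture(small_study.genes[:40], n_reads=50, seed=11)
        sam = tmp_path / "fixture.sam"
        sam.write_text(sam_text)
        table = weighted_gene_counts(sam, small_study.genes[:40])
        got = table.counts.reindex(expected.counts.index)
        assert (got == expected.counts).all()
        assert table.total_mapped_reads == expected.total_mapped_reads

    def test_missing_nh_treated_as_unique_with_warning(self, tmp_path, caplog):
        sam = tmp_path / "nonh.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:Chr1\tLN:10000\n"
            "r1\t0\tChr1\t1100\t255\t90M\t*\t0\t0\t*\t*\n"
        )
        with caplog.at_level(logging.WARNING):
            recs = list(iter_sam(sam))
        assert recs[0].n_hits == 1
        assert any("NH" in m for m in caplog.messages)

    def test_count_table_round_trip(self, tmp_path, toy_genes):
        table = weighted_gene_counts([_rec("r1", "Chr1", 1100, 90, nh=2)], toy_genes)
        path = tmp_path / "counts.tsv"
        table.write(path)
        back = CountTable.read(path)
        assert back.total_mapped_reads == table.total_mapped_reads
        assert (back.counts == table.counts).all()


class TestExpressionProfile:
    def test_rpkm_columns_consistent(self, toy_genes):
        recs = [_rec(f"r{i}", "Chr1", 1100, 90) for i in range(4)]
        table = weighted_gene_counts(recs, toy_genes)
        profile = expression_profile(table, toy_genes)
        # gA: 4 reads on a 1 kb exon model out of 4 mapped reads
        assert profile.loc["gA", "rpkm"] == pytest.approx(4 / (1.0 * 4e-6))
        assert profile.loc["gA", "rpb"] == pytest.approx(1e9)
        assert profile["rpkm"].drop("gA").eq(0).all()
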