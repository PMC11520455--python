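"""Gap-threshold chaining, length filtering and fragment classification."""

import numpy as np
import pytest

from conftest import brute_force_assembly, make_record, random_instance
from syntenica.assembly import (
    assemble_fragments,
    classify_fragments,
    filter_fragments,
    full_gene_extension,
    records_for_query,
    resolve_query,
)
from syntenica.formats import GeneModel


def gene(gene_id, start, end, seq_id="chrT", species="sp"):
    return GeneModel(gene_id=gene_id, species=species, seq_id=seq_id,
                     start=start, end=end, strand="+")


class TestAssemble:
    def test_gap_bridged_at_threshold(self):
        recs = [make_record(100, 200), make_record(210, 300)]
        frags = assemble_fragments(recs, gap_value=10)
        assert len(frags) == 1
        assert frags[0].t_span == (100, 300)
        assert frags[0].members == (0, 1)

    def test_gap_not_bridged_below_threshold(self):
        recs = [make_record(100, 200), make_record(210, 300)]
        assert len(assemble_fragments(recs, gap_value=9)) == 2

    def test_abutting_blocks_merge_at_zero_gap(self):
        recs = [make_record(100, 200), make_record(200, 300)]
        frags = assemble_fragments(recs, gap_value=0)
        assert len(frags) == 1 and frags[0].t_span == (100, 300)

    @pytest.mark.parametrize("gap", [0, 10, 10_000])
    def test_different_target_sequences_never_merge(self, gap):
        recs = [make_record(100, 200, t_name="chr1"), make_record(100, 200, t_name="chr2")]
        assert len(assemble_fragments(recs, gap)) == 2

    def test_different_strands_never_merge(self):
        recs = [make_record(100, 200, strand="+"), make_record(210, 300, strand="-")]
        assert len(assemble_fragments(recs, 10_000)) == 2

    def test_mixed_query_names_rejected(self):
        recs = [make_record(0, 10, q_name="a"), make_record(20, 30, q_name="b")]
        with pytest.raises(ValueError, match="multiple query sequences"):
            assemble_fragments(recs, 10)

    def test_matches_chain_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            records, gap = random_instance(rng)
            frags = assemble_fragments(records, gap)
            got = sorted(
                (f.t_seq, f.strand, f.t_start, f.t_end, frozenset(f.members))
                for f in frags
            )
            assert got == brute_force_assembly(records, gap)

    def test_aggregate_matches_conserved(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            records, gap = random_instance(rng)
            frags = assemble_fragments(records, gap)
            assert sum(f.aggregate["matches"] for f in frags) == sum(
                r.matches for r in records
            )

    def test_fragment_count_non_increasing_in_gap(self):
        rng = np.random.default_rng(13)
        records, _ = random_instance(rng, max_records=8)
        counts = [len(assemble_fragments(records, g)) for g in range(0, 1001, 50)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestFilter:
    def test_threshold_is_inclusive(self):
        frags = assemble_fragments([make_record(0, 160)], 0)
        retained, discarded = filter_fragments(frags, query_len=1000, filtering_pct=16)
        assert len(retained) == 1 and not discarded

    def test_zero_pct_retains_all(self):
        frags = assemble_fragments([make_record(0, 5), make_record(100, 101)], 0)
        retained, _ = filter_fragments(frags, 1000, 0)
        assert len(retained) == 2

    def test_threshold_arithmetic(self):
        frags = assemble_fragments([make_record(0, 500), make_record(2000, 2100)], 0)
        retained, discarded = filter_fragments(frags, 1000, 16)
        assert [f.length for f in retained] == [500]
        assert [f.length for f in discarded] == [100]


class TestClassify:
    def test_single_fragment_is_primary(self):
        frags = assemble_fragments([make_record(100, 500)], 0)
        fset = classify_fragments(frags, [gene("gA", 100, 600)], species="sp")
        assert fset.primary is frags[0]
        assert not fset.co_gene and not fset.secondary

    def test_same_gene_fragment_is_co_gene(self):
        frags = assemble_fragments([make_record(100, 400), make_record(700, 800)], 0)
        fset = classify_fragments(frags, [gene("gA", 50, 900)], species="sp")
        assert fset.primary.t_span == (100, 400)
        assert [f.t_span for f in fset.co_gene] == [(700, 800)]

    def test_other_gene_fragment_is_secondary(self):
        frags = assemble_fragments([make_record(100, 400), make_record(700, 800)], 0)
        genes = [gene("gA", 50, 450), gene("gB", 650, 900)]
        fset = classify_fragments(frags, genes, species="sp")
        assert [f.t_span for f in fset.secondary] == [(700, 800)]

    def test_empty_retained_is_legal(self):
        fset = classify_fragments([], [gene("gA", 0, 10)], species="sp")
        assert fset.primary is None and fset.displayed() == []


class TestFullGeneExtension:
    def test_extends_to_gene_ends(self):
        (f,) = assemble_fragments([make_record(150, 400)], 0)
        out = full_gene_extension(f, [gene("gA", 100, 500)])
        assert out.t_span == (100, 500)
        assert out.aggregate == f.aggregate

    def test_intergenic_fragment_unchanged(self):
        (f,) = assemble_fragments([make_record(150, 400)], 0)
        assert full_gene_extension(f, [gene("gA", 1000, 2000)]) is f

    def test_spanning_two_genes_takes_hull(self):
        (f,) = assemble_fragments([make_record(250, 650)], 0)
        out = full_gene_extension(f, [gene("gA", 100, 300), gene("gB", 600, 900)])
        assert out.t_span == (100, 900)

    def test_idempotent(self):
        genes = [gene("gA", 100, 300), gene("gB", 280, 900), gene("gC", 950, 1200)]
        (f,) = assemble_fragments([make_record(150, 200)], 0)
        once = full_gene_extension(f, genes)
        assert full_gene_extension(once, genes).t_span == once.t_span


class TestResolveQuery:
    ANNOT = [gene("unc-1", 1000, 3000, seq_id="I")]
    GENOME = {"I": 10_000}

    def test_gene_name_resolves_to_span(self):
        region = resolve_query("unc-1", self.ANNOT, self.GENOME, "ref")
        assert (region.seq_id, region.start, region.end) == ("I", 1000, 3000)

    def test_coordinates_one_based_closed(self):
        region = resolve_query("I:101-200", self.ANNOT, self.GENOME, "ref")
        assert (region.start, region.end) == (100, 200)
        region = resolve_query("I:101..200", self.ANNOT, self.GENOME, "ref")
        assert (region.start, region.end) == (100, 200)

    @pytest.mark.parametrize("q", ["I:100..50", "I:0-10", "I:1-20000", "II:1-10", "nope"])
    def test_invalid_queries_rejected(self, q):
        with pytest.raises(ValueError):
            resolve_query(q, self.ANNOT, self.GENOME, "ref")

    def test_records_for_query_filters_by_overlap(self):
        region = resolve_query("unc-1", self.ANNOT, self.GENOME, "ref")
        inside = make_record(0, 100, q_start=1500, q_name="I")
        outside = make_record(0, 100, q_start=5000, q_name="I")
        other_seq = make_record(0, 100, q_start=1500, q_name="II")
        assert records_for_query([inside, outside, other_seq], region) == [inside]
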