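"""The clade simulator: coordinate maps, liftover fragmentation, ground truth."""

import pytest
from hypothesis import given, settings, strategies as st

from syntenica.formats import write_psl
from syntenica.simulate import (
    AncGene,
    Copy,
    Placement,
    SimConfig,
    coord_segments,
    fragment_alignments,
    map_interval,
    simulate_clade,
    survival_runs,
)


# ---------------------------------------------------------------------------
# coordinate maps against a base-by-base oracle
# ---------------------------------------------------------------------------


def oracle_local_positions(anc_len, dels, ins):
    """Materialize the edited gene base-by-base: ancestral base -> local pos.

    Returns (mapping, local_length) where mapping[a] is the local position
    of surviving ancestral base a.
    """
    deleted = set()
    for p, s in dels:
        deleted.update(range(p, p + s))
    ins_at = {}
    for p, s in ins:
        ins_at[p] = ins_at.get(p, 0) + s
    mapping = {}
    local = 0
    for a in range(anc_len + 1):
        local += ins_at.get(a, 0)
        if a < anc_len and a not in deleted:
            mapping[a] = local
            local += 1
    return mapping, local


@st.composite
def indel_sets(draw):
    anc_len = draw(st.integers(50, 400))
    n_del = draw(st.integers(0, 3))
    dels = []
    for _ in range(n_del):
        p = draw(st.integers(0, anc_len - 2))
        s = draw(st.integers(1, 30))
        if any(p < dp + ds and dp < p + s for dp, ds in dels):
            continue
        if p + s <= anc_len:
            dels.append((p, s))
    deleted = {b for p, s in dels for b in range(p, p + s)}
    n_ins = draw(st.integers(0, 3))
    ins = []
    for _ in range(n_ins):
        p = draw(st.integers(0, anc_len))
        if p in deleted or any(p == q for q, _ in ins):
            continue
        ins.append((p, draw(st.integers(1, 30))))
    return anc_len, sorted(dels), sorted(ins)


@settings(max_examples=150, derandomize=True)
@given(indel_sets())
def test_coord_segments_match_per_base_oracle(case):
    anc_len, dels, ins = case
    segs, local_len = coord_segments(anc_len, dels, ins)
    mapping, oracle_len = oracle_local_positions(anc_len, dels, ins)
    assert local_len == oracle_len
    for a0, a1, l0 in segs:
        for a in range(a0, a1):
            assert mapping[a] == l0 + (a - a0)
    # every surviving base is covered by exactly one segment
    covered = sum(a1 - a0 for a0, a1, _ in segs)
    assert covered == len(mapping)


@settings(max_examples=60, derandomize=True)
@given(indel_sets(), st.data())
def test_map_interval_is_hull_of_survivors(case, data):
    anc_len, dels, ins = case
    segs, _ = coord_segments(anc_len, dels, ins)
    mapping, _ = oracle_local_positions(anc_len, dels, ins)
    a0 = data.draw(st.integers(0, anc_len - 1))
    a1 = data.draw(st.integers(a0 + 1, anc_len))
    got = map_interval(segs, a0, a1)
    survivors = [mapping[a] for a in range(a0, a1) if a in mapping]
    if not survivors:
        assert got is None
    else:
        assert got == (min(survivors), max(survivors) + 1)


def test_survival_runs_complement_deletions():
    assert survival_runs(100, [(10, 5), (50, 10)]) == [(0, 10), (15, 50), (60, 100)]
    assert survival_runs(100, []) == [(0, 100)]


# ---------------------------------------------------------------------------
# liftover fragmentation
# ---------------------------------------------------------------------------


def toy_placement(chrom, offset, dels=(), ins=(), orientation=1, anc_len=1000,
                  chrom_len=100_000, species="sp"):
    anc = AncGene("g", "OG", anc_len, (), (), (), (), ())
    c = Copy(anc, "g", None, 0, tuple(dels), tuple(ins), orientation,
             "ortholog", None, False)
    segs, llen = coord_segments(anc_len, dels, ins)
    return Placement(copy=c, species=species, chrom=chrom, chrom_len=chrom_len,
                     offset=offset, segs=tuple(segs), local_len=llen)


CFG = SimConfig()


class TestFragmentAlignments:
    def test_no_indels_one_record(self):
        q = toy_placement("q_chr", 5000)
        t = toy_placement("t_chr", 8000)
        (rec,) = fragment_alignments(q, t, subs=10, cfg=CFG)
        assert rec.blockCount == 1 and rec.aligned_bases == 1000
        assert (rec.qStart, rec.qEnd) == (5000, 6000)
        assert (rec.tStart, rec.tEnd) == (8000, 9000)
        assert rec.misMatches == 10 and rec.matches == 990

    def test_insertion_in_target_makes_two_records_with_gap(self):
        q = toy_placement("q_chr", 0)
        t = toy_placement("t_chr", 0, ins=[(500, 30)])
        recs = sorted(fragment_alignments(q, t, 0, CFG), key=lambda r: r.tStart)
        assert len(recs) == 2
        assert recs[1].tStart - recs[0].tEnd == 30  # target gap == indel size
        assert recs[1].qStart - recs[0].qEnd == 0   # query is contiguous

    def test_deletion_in_target_makes_query_side_gap(self):
        q = toy_placement("q_chr", 0)
        t = toy_placement("t_chr", 0, dels=[(500, 40)])
        recs = sorted(fragment_alignments(q, t, 0, CFG), key=lambda r: r.tStart)
        assert len(recs) == 2
        assert recs[1].tStart - recs[0].tEnd == 0
        assert recs[1].qStart - recs[0].qEnd == 40

    def test_shared_indel_stays_one_record(self):
        q = toy_placement("q_chr", 0, ins=[(500, 30)])
        t = toy_placement("t_chr", 0, ins=[(500, 30)])
        # identical insertions: still a single contiguous alignment
        recs = fragment_alignments(q, t, 0, CFG)
        assert len(recs) == 2  # the inserted bases themselves are unalignable
        assert recs[1].tStart - recs[0].tEnd == 30
        assert recs[1].qStart - recs[0].qEnd == 30

    def test_min_block_drops_short_fragment(self):
        q = toy_placement("q_chr", 0)
        t = toy_placement("t_chr", 0, ins=[(990, 25)])  # trailing 10 bp fragment
        recs = fragment_alignments(q, t, 0, CFG)
        assert len(recs) == 1 and recs[0].aligned_bases == 990

    def test_inverted_copy_gives_minus_strand_records(self):
        q = toy_placement("q_chr", 5000)
        t = toy_placement("t_chr", 8000, orientation=-1)
        (rec,) = fragment_alignments(q, t, 0, CFG)
        assert rec.strand == "-"
        rec.validate()
        assert rec.query_blocks() == [(5000, 6000)]


# ---------------------------------------------------------------------------
# whole-clade properties
# ---------------------------------------------------------------------------


class TestNullEvolution:
    def test_species_are_identical_and_single_copy(self, null_clade):
        clade = null_clade
        lengths = {sp: list(v.values())[0] for sp, v in clade.genomes.items()}
        assert len(set(lengths.values())) == 1
        ref = clade.reference
        ref_spans = [(g.start, g.end, g.exons) for g in clade.annotations[ref]]
        for sp in clade.species:
            spans = [(g.start, g.end, g.exons) for g in clade.annotations[sp]]
            assert spans == ref_spans
        assert len(clade.truth["gene_classes"]["single_copy"]) == clade.config.n_genes

    def test_one_full_length_alignment_per_gene_per_species(self, null_clade):
        clade = null_clade
        genes = {g.gene_id.split("_", 1)[1]: g for g in
                 clade.annotations[clade.reference]}
        for sp, records in clade.alignments.items():
            assert len(records) == clade.config.n_genes
            for rec in records:
                assert rec.blockCount == 1 and rec.misMatches == 0
                assert rec.qEnd - rec.qStart == rec.aligned_bases

    def test_no_losses_gaps_or_duplications(self, null_clade):
        t = null_clade.truth
        assert t["losses"] == [] and t["annotation_gaps"] == []
        assert t["parent_daughter"] == []


class TestEngineeredEvents:
    def test_recent_tandem_duplication_bookkeeping(self):
        cfg = SimConfig(seed=3, n_genes=8, n_ancient_dups=0, n_old_dups=0,
                        n_recent_dups=1, tandem_fraction=1.0)
        clade = simulate_clade(cfg)
        (pd,) = clade.truth["parent_daughter"]
        ref_genes = clade.genes_by_id(clade.reference)
        parent, daughter = ref_genes[pd["parent"]], ref_genes[pd["daughter"]]
        # tandem: adjacent on the reference chromosome, parent first
        assert parent.seq_id == daughter.seq_id
        between = [
            g for g in clade.annotations[clade.reference]
            if parent.end <= g.start < daughter.start or
               daughter.end <= g.start < parent.start
        ]
        assert between == []
        # other species carry a single ortholog of that orthogroup
        og = pd["orthogroup"]
        for sp in clade.species:
            n = len(clade.orthogroups.members(og).get(sp, []))
            assert n == (2 if sp == clade.reference else 1)

    def test_forced_loss_removes_gene_and_is_recorded(self):
        cfg = SimConfig(
            seed=9, n_genes=6, n_ancient_dups=1, n_old_dups=0, n_recent_dups=1,
            loss_prob=0.0, annotation_gap_prob=0.0,
            rate_overrides={"spE": {"loss_prob": 1.0}},
        )
        clade = simulate_clade(cfg)
        lost_ogs = {e["orthogroup"] for e in clade.truth["losses"]
                    if e["species"] == "spE"}
        assert len(lost_ogs) == 4  # the whole single-copy pool on that branch
        spE_ogs = {g.orthogroup_id for g in clade.annotations["spE"]}
        assert lost_ogs.isdisjoint(spE_ogs)
        # lost genes also have no alignments in spE
        spE_targets = {r.tName for r in clade.alignments["spE"]}
        assert spE_targets <= {"spE_chr1"}
        for e in clade.truth["losses"]:
            if e["species"] != "spE":
                continue
            ref_gene = clade.genes_by_id(clade.reference)[e["ref_gene"]]
            hits = [
                r for r in clade.alignments["spE"]
                if r.qStart < ref_gene.end and r.qEnd > ref_gene.start
            ]
            assert hits == []

    def test_annotation_gap_keeps_alignment(self, golden_dataset):
        gaps = golden_dataset.truth["annotation_gaps"]
        assert gaps, "golden fixture should contain annotation gaps"
        for e in gaps:
            sp = e["species"]
            annotated = {g.gene_id for g in golden_dataset.annotations[sp]}
            assert not any(gid.endswith(e["orthogroup"]) for gid in annotated)
            ref_gene = golden_dataset.genes_by_id(golden_dataset.reference)[
                e["ref_gene"]
            ]
            hits = [
                r for r in golden_dataset.alignments[sp]
                if r.qStart < ref_gene.end and r.qEnd > ref_gene.start
            ]
            assert hits, "alignment must survive an annotation gap"


class TestDeterminismAndConsistency:
    def test_same_seed_reproduces_everything(self):
        cfg = SimConfig(seed=21, n_genes=20)
        a, b = simulate_clade(cfg), simulate_clade(cfg)
        assert a.truth == b.truth
        for sp in a.alignments:
            assert write_psl(a.alignments[sp]) == write_psl(b.alignments[sp])

    def test_emitted_psl_parses_and_validates(self, golden_dataset):
        for sp, records in golden_dataset.alignments.items():
            for r in records:
                r.validate()
        total = sum(len(v) for v in golden_dataset.pairwise.values())
        assert total > 0

    def test_empty_configuration_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            simulate_clade(SimConfig(n_genes=0))

    def test_truth_covers_every_reference_gene(self, golden_dataset):
        classes = golden_dataset.truth["gene_classes"]
        listed = [g for ids in classes.values() for g in ids]
        assert len(listed) == len(set(listed))
        ref_ids = {g.gene_id for g in
                   golden_dataset.annotations[golden_dataset.reference]}
        assert set(listed) == ref_ids
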