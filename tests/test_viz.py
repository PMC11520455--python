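"""Query pipeline, plotting, missing-ortholog flagging and sweeps."""

import pytest

from syntenica.simulate import SimConfig, simulate_clade
from syntenica.viz import (
    PlotOptions,
    aligned_genes_table,
    detect_missing_ortholog,
    orthogroup_color,
    render_plot,
    run_query,
    save_plot,
    scan_missing_orthologs,
    single_copy_concordance,
    sweep_parameters,
)


@pytest.fixture(scope="module")
def null_query(null_clade):
    gid = null_clade.annotations[null_clade.reference][3].gene_id
    return gid, run_query(null_clade, gid)


class TestRunQuery:
    def test_every_species_has_the_ortholog_fragment(self, null_clade, null_query):
        gid, result = null_query
        for sp in null_clade.species:
            fset = result.fragment_sets[sp]
            assert fset.primary is not None
            assert not fset.secondary
        ref_fragment = result.fragment_sets[null_clade.reference].primary
        assert (ref_fragment.t_start, ref_fragment.t_end) == (
            result.region.start, result.region.end
        )

    def test_links_connect_all_adjacent_pairs(self, null_clade, null_query):
        _, result = null_query
        pairs = {(ln.species_a, ln.species_b) for ln in result.links}
        assert pairs == set(null_clade.tree.adjacent_pairs())

    def test_aligned_genes_table_lists_orthologs(self, null_clade, null_query):
        gid, result = null_query
        text = aligned_genes_table(result, null_clade)
        rows = [r.split("\t") for r in text.strip().splitlines()[1:]]
        assert len(rows) == len(null_clade.species)
        og = null_clade.orthogroups.og_of(gid)
        assert all(r[6] == og and r[7] == "top" for r in rows)

    def test_secondary_fragment_for_tandem_paralog(self):
        clade = simulate_clade(
            SimConfig(seed=3, n_genes=8, n_ancient_dups=0, n_old_dups=0,
                      n_recent_dups=0, loss_prob=0, annotation_gap_prob=0,
                      rate_overrides={"spB": {"dup_rate": 0.0}})
        )
        # duplicate in a partner species: query its reference ortholog and the
        # daughter fragment must land in the secondary (bottom) panel
        clade2 = simulate_clade(
            SimConfig(seed=3, n_genes=8, n_ancient_dups=1, n_old_dups=0,
                      n_recent_dups=0, tandem_fraction=1.0,
                      loss_prob=0, annotation_gap_prob=0)
        )
        og = next(iter({
            e for e in clade2.truth["gene_classes"]["ancient"]
        }))
        result = run_query(clade2, og, filtering_pct=0)
        any_extra = any(
            fset.co_gene or fset.secondary
            for sp, fset in result.fragment_sets.items()
            if sp != clade2.reference
        )
        assert any_extra


class TestRenderPlot:
    def test_plot_is_deterministic(self, null_clade, null_query, tmp_path):
        _, result = null_query
        paths = []
        for i in (1, 2):
            fig = render_plot(result, null_clade)
            p = tmp_path / f"plot{i}.svg"
            save_plot(fig, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]
        assert b"<svg" in paths[0]

    def test_microsynteny_draws_one_glyph_per_exon(self, null_clade, null_query):
        gid, result = null_query
        fig = render_plot(result, null_clade, PlotOptions(microsynteny=True))
        exon_glyphs = [
            p for ax in fig.axes for p in ax.patches if p.get_gid() == "exon"
        ]
        suffix = gid.split("_", 1)[1]
        expected = sum(
            len(g.exons)
            for sp in null_clade.species
            for g in null_clade.annotations[sp]
            if g.gene_id.endswith(suffix)
        )
        assert len(exon_glyphs) == expected

    def test_empty_fragment_sets_still_render_with_notice(self, null_clade,
                                                          null_query, tmp_path):
        gid, result = null_query
        for sp in list(result.fragment_sets):
            if sp != null_clade.reference:
                result.fragment_sets[sp].primary = None
                result.fragment_sets[sp].co_gene = []
        result.links = []
        fig = render_plot(result, null_clade)
        assert "no retained fragment" in fig.axes[0].get_title()
        save_plot(fig, tmp_path / "sparse.svg")

    def test_orthogroup_colors_deterministic_and_distinct(self):
        assert orthogroup_color("OG1") == orthogroup_color("OG1")
        assert orthogroup_color("OG1") != orthogroup_color("OG2")


class TestMissingOrtholog:
    def test_losses_and_gaps_flagged_exactly(self, golden_dataset):
        flags = scan_missing_orthologs(golden_dataset)
        got_loss = {(f.species, f.orthogroup) for f in flags if f.kind == "loss"}
        got_gap = {(f.species, f.orthogroup) for f in flags
                   if f.kind == "annotation_gap"}
        want_loss = {(e["species"], e["orthogroup"])
                     for e in golden_dataset.truth["losses"]}
        want_gap = {(e["species"], e["orthogroup"])
                    for e in golden_dataset.truth["annotation_gaps"]}
        assert got_loss == want_loss
        assert got_gap == want_gap

    def test_gap_candidate_interval_overlaps_true_gene(self, golden_dataset):
        truth = {(e["species"], e["orthogroup"]): e
                 for e in golden_dataset.truth["annotation_gaps"]}
        for f in scan_missing_orthologs(golden_dataset):
            if f.kind != "annotation_gap":
                continue
            e = truth[(f.species, f.orthogroup)]
            t0, t1 = e["interval"]
            assert f.seq_id == e["seq"]
            assert f.start < t1 and f.end > t0

    def test_fully_annotated_orthogroup_reports_nothing(self, null_clade):
        og = null_clade.annotations[null_clade.reference][0].orthogroup_id
        assert detect_missing_ortholog(og, null_clade) == []

    def test_unknown_orthogroup_rejected(self, null_clade):
        with pytest.raises(KeyError):
            detect_missing_ortholog("OG9999", null_clade)


class TestSweeps:
    def test_null_fixture_fraction_one_everywhere(self, null_clade):
        queries = [g.gene_id for g in null_clade.annotations[null_clade.reference]]
        curves = sweep_parameters(null_clade, queries,
                                  gap_grid=[0, 100, 1000], pct_grid=[0, 16, 50])
        assert curves["fraction_single_fragment"] == [1.0, 1.0, 1.0]
        assert curves["mean_retained_per_species"] == [1.0, 1.0, 1.0]

    def test_full_pct_with_short_fragments_gives_zero(self, null_clade):
        # querying a region twice the gene span leaves every fragment short
        ref = null_clade.reference
        g = null_clade.annotations[ref][0]
        chrom = g.seq_id
        query = f"{chrom}:{g.start + 1}-{min(g.end + g.length * 3, list(null_clade.genomes[ref].values())[0])}"
        curves = sweep_parameters(null_clade, [query], gap_grid=[0],
                                  pct_grid=[100])
        assert curves["mean_retained_per_species"] == [0.0]

    def test_monotonicity_on_golden(self, golden_dataset):
        queries = golden_dataset.truth["gene_classes"]["single_copy"][:30]
        curves = sweep_parameters(golden_dataset, queries)
        frac = curves["fraction_single_fragment"]
        mean = curves["mean_retained_per_species"]
        assert all(b >= a for a, b in zip(frac, frac[1:]))
        assert all(b <= a for a, b in zip(mean, mean[1:]))

    def test_empty_grid_rejected(self, golden_dataset):
        with pytest.raises(ValueError):
            sweep_parameters(golden_dataset, ["x"], gap_grid=[], pct_grid=[0])


def test_single_copy_concordance_is_high_on_golden(golden_dataset):
    singles = golden_dataset.truth["gene_classes"]["single_copy"]
    assert single_copy_concordance(golden_dataset, singles) >= 0.99
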