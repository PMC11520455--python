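"""Query pipeline, synteny plots, ortholog-loss flagging and parameter sweeps.

``run_query`` glues the stages together: resolve the query on the
reference annotation, assemble and filter each species' liftover
fragments, classify them, and build links between display-adjacent
tracks.  ``render_plot`` draws the result as tree-ordered tracks with
genes colored by orthogroup (macrosynteny) or exon/intron glyphs
(microsynteny), a top panel for the primary and co-gene fragments and a
bottom panel for secondary "(filtered)" fragments.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "syntenica"

import matplotlib.pyplot as plt
from matplotlib.colors import hsv_to_rgb
from matplotlib.patches import FancyArrow, Polygon, Rectangle

from .assembly import (
    AssembledFragment,
    FragmentSet,
    QueryRegion,
    assemble_fragments,
    classify_fragments,
    filter_fragments,
    full_gene_extension,
    overlapping_genes,
    records_for_query,
    resolve_query,
)
from .formats import Dataset, GeneModel
from .links import SyntenyLink, build_links

logger = logging.getLogger("syntenica")


def orthogroup_color(og_id: str | None) -> tuple[float, float, float]:
    """Deterministic orthogroup color from a hash of the orthogroup id."""
    if not og_id:
        return (0.65, 0.65, 0.65)
    h = int.from_bytes(hashlib.md5(og_id.encode()).digest()[:4], "big")
    hue = (h % 360) / 360.0
    return tuple(hsv_to_rgb((hue, 0.55, 0.85)))


@dataclass
class QueryResult:
    region: QueryRegion
    fragment_sets: dict[str, FragmentSet]
    links: list[SyntenyLink]
    params: dict


def _reference_fragment(region: QueryRegion, species: str) -> AssembledFragment:
    zeros = {k: 0 for k in (
        "matches", "misMatches", "repMatches", "nCount",
        "qNumInsert", "qBaseInsert", "tNumInsert", "tBaseInsert",
    )}
    zeros["matches"] = region.length
    return AssembledFragment(
        target_species=species, t_seq=region.seq_id, t_start=region.start,
        t_end=region.end, strand="+", q_seq=region.seq_id,
        q_start=region.start, q_end=region.end, members=(),
        aggregate=zeros, aligned_bases=region.length,
    )


def run_query(
    dataset: Dataset,
    query: str,
    gap_value: int = 200,
    filtering_pct: float = 16.0,
    full_gene_ext: bool = False,
    clip_links: bool = True,
) -> QueryResult:
    """Run the whole pipeline for one query on a loaded dataset."""
    ref = dataset.reference
    region = resolve_query(query, dataset.annotations[ref], dataset.genomes[ref], ref)
    fragment_sets: dict[str, FragmentSet] = {}
    for sp in dataset.species:
        if sp == ref:
            fset = FragmentSet(species=ref, primary=_reference_fragment(region, ref))
            fragment_sets[ref] = fset
            continue
        records = records_for_query(dataset.alignments.get(sp, []), region)
        fragments = assemble_fragments(records, gap_value, species=sp)
        retained, discarded = filter_fragments(fragments, region.length, filtering_pct)
        fset = classify_fragments(retained, dataset.annotations.get(sp, []),
                                  species=sp, discarded=discarded)
        if full_gene_ext:
            genes = dataset.annotations.get(sp, [])
            if fset.primary is not None:
                fset.primary = full_gene_extension(fset.primary, genes)
            fset.co_gene = [full_gene_extension(f, genes) for f in fset.co_gene]
            fset.secondary = [full_gene_extension(f, genes) for f in fset.secondary]
        fragment_sets[sp] = fset
    links = build_links(
        fragment_sets, dataset.tree.display_order, dataset.pairwise, gap_value,
        clip=clip_links,
    )
    return QueryResult(
        region=region, fragment_sets=fragment_sets, links=links,
        params={"gap_value": gap_value, "filtering_pct": filtering_pct,
                "full_gene_extension": full_gene_ext},
    )


def aligned_genes_table(result: QueryResult, dataset: Dataset) -> str:
    """Genes overlapped by the displayed fragments, with panel assignment."""
    lines = ["species\tgene_id\tseq_id\tstart\tend\tstrand\torthogroup\tpanel"]
    for sp in dataset.species:
        fset = result.fragment_sets.get(sp)
        if fset is None:
            continue
        rows: list[tuple[GeneModel, str]] = []
        top = ([fset.primary] if fset.primary else []) + fset.co_gene
        for f in top:
            for g in overlapping_genes(f, dataset.annotations.get(sp, [])):
                rows.append((g, "top"))
        for f in fset.secondary:
            for g in overlapping_genes(f, dataset.annotations.get(sp, [])):
                rows.append((g, "bottom"))
        seen = set()
        for g, panel in rows:
            if (g.gene_id, panel) in seen:
                continue
            seen.add((g.gene_id, panel))
            lines.append(
                f"{sp}\t{g.gene_id}\t{g.seq_id}\t{g.start}\t{g.end}\t{g.strand}"
                f"\t{g.orthogroup_id or ''}\t{panel}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------


@dataclass
class PlotOptions:
    microsynteny: bool = False
    show_links: bool = True
    figsize: tuple[float, float] = (11.0, 0.0)  # height auto if 0
    pad_bp: int = 500  # spacing between fragments on one track


class _TrackLayout:
    """x placement of displayed fragments on one species track."""

    def __init__(self, fragments: Sequence[AssembledFragment], pad: int):
        self.offsets: list[tuple[AssembledFragment, int]] = []
        x = 0
        for f in fragments:
            self.offsets.append((f, x))
            x += f.length + pad
        self.width = max(0, x - pad)

    def to_x(self, seq: str, pos: int) -> float | None:
        for f, off in self.offsets:
            if f.t_seq == seq and f.t_start <= pos <= f.t_end:
                return off + (pos - f.t_start)
        return None


def _draw_gene(ax, g: GeneModel, f: AssembledFragment, off: int, y: float,
               micro: bool) -> int:
    """Draw one gene clipped to its fragment; returns glyph count."""

    def to_x(pos: int) -> float:
        return off + (min(max(pos, f.t_start), f.t_end) - f.t_start)

    x0, x1 = to_x(g.start), to_x(g.end)
    if x1 <= x0:
        return 0
    color = orthogroup_color(g.orthogroup_id)
    n = 0
    if micro:
        ax.plot([x0, x1], [y, y], color="0.3", lw=0.8, zorder=2)
        for s, e in sorted(g.exons):
            xs, xe = to_x(s), to_x(e)
            if xe <= xs:
                continue
            ax.add_patch(
                Rectangle((xs, y - 0.12), xe - xs, 0.24, facecolor=color,
                          edgecolor="black", lw=0.4, zorder=3, gid="exon")
            )
            n += 1
    else:
        dx = x1 - x0
        if g.strand == "-":
            x0, dx = x1, -dx
        ax.add_patch(
            FancyArrow(
                x0, y, dx, 0, width=0.24, head_width=0.24,
                head_length=min(abs(dx) * 0.25, 200), length_includes_head=True,
                facecolor=color, edgecolor="black", lw=0.4, zorder=3, gid="gene",
            )
        )
        n += 1
    return n


def render_plot(
    result: QueryResult,
    dataset: Dataset,
    options: PlotOptions | None = None,
):
    """Render the synteny plot; returns the matplotlib figure.

    Tracks follow the species-tree display order; the primary and co-gene
    fragments sit on the track line, secondary fragments on a lower
    sub-row labeled "(filtered)"; links connect adjacent tracks, crossing
    when inverted.
    """
    options = options or PlotOptions()
    order = dataset.tree.display_order
    n = len(order)
    height = options.figsize[1] or max(3.0, 0.9 * n)
    fig, ax = plt.subplots(figsize=(options.figsize[0], height))
    layouts: dict[str, _TrackLayout] = {}
    ys: dict[str, float] = {}
    empty_tracks = []
    for i, sp in enumerate(order):
        y = n - 1 - i
        ys[sp] = y
        fset = result.fragment_sets.get(sp)
        top = ([fset.primary] if fset and fset.primary else []) + (fset.co_gene if fset else [])
        layouts[sp] = _TrackLayout(top + (fset.secondary if fset else []), options.pad_bp)
        if not top:
            empty_tracks.append(sp)
        genes = dataset.annotations.get(sp, [])
        n_top = len(top)
        for j, (f, off) in enumerate(layouts[sp].offsets):
            sub = j >= n_top  # secondary fragments drop to the bottom sub-row
            yy = y - (0.38 if sub else 0.0)
            ax.add_patch(
                Rectangle((off, yy - 0.06), f.length, 0.12, facecolor="0.85",
                          edgecolor="0.5", lw=0.5, zorder=1, gid="fragment")
            )
            if sub:
                ax.text(off + f.length, yy + 0.08, "(filtered)", fontsize=6,
                        ha="right", color="0.35")
            for g in overlapping_genes(f, genes):
                _draw_gene(ax, g, f, off, yy, options.microsynteny)
        ax.text(-0.01, y, sp, transform=ax.get_yaxis_transform(), ha="right",
                va="center", fontsize=9)
    if options.show_links:
        for ln in result.links:
            la, lb = layouts.get(ln.species_a), layouts.get(ln.species_b)
            if la is None or lb is None:
                continue
            ax0 = la.to_x(ln.seq_a, ln.start_a)
            ax1 = la.to_x(ln.seq_a, ln.end_a)
            bx0 = lb.to_x(ln.seq_b, ln.start_b)
            bx1 = lb.to_x(ln.seq_b, ln.end_b)
            if None in (ax0, ax1, bx0, bx1):
                continue
            if ln.strand_relation == "inverted":
                bx0, bx1 = bx1, bx0
            ya, yb = ys[ln.species_a] - 0.1, ys[ln.species_b] + 0.1
            ax.add_patch(
                Polygon(
                    [(ax0, ya), (ax1, ya), (bx1, yb), (bx0, yb)],
                    closed=True, facecolor="#9ecae1", alpha=0.55, edgecolor="none",
                    zorder=0, gid="link",
                )
            )
    if empty_tracks:
        ax.set_title(
            "no retained fragment for: " + ", ".join(empty_tracks), fontsize=8
        )
    ax.set_ylim(-1, n)
    ax.set_xlim(0, max(l.width for l in layouts.values()) * 1.02 + 1)
    ax.set_yticks([])
    ax.set_xlabel("position within assembled fragments (bp)")
    fig.tight_layout()
    return fig


def save_plot(fig, path) -> None:
    """Write the figure deterministically (no timestamps in SVG output)."""
    path = str(path)
    meta = {"Date": None} if path.endswith(".svg") else None
    fig.savefig(path, metadata=meta)
    plt.close(fig)


# ---------------------------------------------------------------------------
# missing-ortholog flagging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MissingOrtholog:
    """A species lacking an annotated member of an orthogroup.

    ``kind`` is 'annotation_gap' when a retained fragment still aligns to
    the expected syntenic interval (candidate unannotated gene) and
    'loss' when no fragment aligns at all (gene loss or deep divergence).
    """

    species: str
    orthogroup: str
    kind: str
    seq_id: str | None = None
    start: int | None = None
    end: int | None = None


def detect_missing_ortholog(
    og_id: str,
    dataset: Dataset,
    gap_value: int = 200,
    filtering_pct: float = 16.0,
) -> list[MissingOrtholog]:
    """Flag species that lack an annotated member of the orthogroup."""
    if og_id not in dataset.orthogroups:
        raise KeyError(f"orthogroup {og_id!r} not in table")
    members = dataset.orthogroups.members(og_id)
    if len([sp for sp, g in members.items() if g]) < 2:
        raise ValueError(f"orthogroup {og_id} has members in fewer than 2 species")
    ref = dataset.reference
    ref_members = members.get(ref, [])
    if not ref_members:
        raise ValueError(f"orthogroup {og_id} has no member in the reference species")
    ref_gene = dataset.genes_by_id(ref)[ref_members[0]]
    region = QueryRegion(ref_gene.seq_id, ref_gene.start, ref_gene.end, ref,
                         source=ref_gene.gene_id)
    flags: list[MissingOrtholog] = []
    for sp in dataset.species:
        if sp == ref or members.get(sp):
            continue
        records = records_for_query(dataset.alignments.get(sp, []), region)
        fragments = assemble_fragments(records, gap_value, species=sp)
        retained, _ = filter_fragments(fragments, region.length, filtering_pct)
        if retained:
            best = retained[0]
            flags.append(
                MissingOrtholog(sp, og_id, "annotation_gap",
                                best.t_seq, best.t_start, best.t_end)
            )
        else:
            flags.append(MissingOrtholog(sp, og_id, "loss"))
    return flags


def scan_missing_orthologs(
    dataset: Dataset, gap_value: int = 200, filtering_pct: float = 16.0
) -> list[MissingOrtholog]:
    """detect_missing_ortholog over every orthogroup with a reference anchor."""
    out: list[MissingOrtholog] = []
    for og_id in sorted(dataset.orthogroups.groups):
        members = dataset.orthogroups.members(og_id)
        if not members.get(dataset.reference):
            continue
        if len([sp for sp, g in members.items() if g]) < 2:
            continue
        out.extend(detect_missing_ortholog(og_id, dataset, gap_value, filtering_pct))
    return out


# ---------------------------------------------------------------------------
# parameter sweeps and concordance
# ---------------------------------------------------------------------------


def _query_regions(dataset: Dataset, queries: Sequence[str]) -> list[QueryRegion]:
    ref = dataset.reference
    return [
        resolve_query(q, dataset.annotations[ref], dataset.genomes[ref], ref)
        for q in queries
    ]


def sweep_parameters(
    dataset: Dataset,
    queries: Sequence[str],
    gap_grid: Sequence[int] = tuple(range(0, 1001, 50)),
    pct_grid: Sequence[float] = tuple(range(0, 51, 2)),
    gap_for_pct: int = 200,
) -> dict:
    """Assembly behaviour across gap values and filtering percentages.

    Returns, per gap value, the fraction of queries assembled into exactly
    one fragment in at least one species (length filter off), and, per
    filtering percentage, the mean number of retained fragments per
    species at the fixed gap value.
    """
    if not gap_grid or not pct_grid:
        raise ValueError("grids must be non-empty")
    regions = _query_regions(dataset, queries)
    others = [sp for sp in dataset.species if sp != dataset.reference]
    per_query_records = [
        {sp: records_for_query(dataset.alignments.get(sp, []), region) for sp in others}
        for region in regions
    ]
    gap_curve = []
    for gap in gap_grid:
        hits = 0
        for region, recs in zip(regions, per_query_records):
            one = False
            for sp in others:
                if recs[sp] and len(assemble_fragments(recs[sp], gap, sp)) == 1:
                    one = True
                    break
            hits += one
        gap_curve.append(hits / len(regions) if regions else 0.0)
    pct_curve = []
    assembled = [
        {sp: assemble_fragments(recs[sp], gap_for_pct, sp) for sp in others}
        for recs in per_query_records
    ]
    for pct in pct_grid:
        counts = []
        for region, frag_map in zip(regions, assembled):
            for sp in others:
                retained, _ = filter_fragments(frag_map[sp], region.length, pct)
                counts.append(len(retained))
        pct_curve.append(sum(counts) / len(counts) if counts else 0.0)
    return {
        "gap_grid": list(gap_grid),
        "fraction_single_fragment": gap_curve,
        "pct_grid": list(pct_grid),
        "mean_retained_per_species": pct_curve,
        "gap_for_pct": gap_for_pct,
    }


def single_copy_concordance(
    dataset: Dataset,
    single_copy_genes: Sequence[str],
    gap_value: int = 200,
    filtering_pct: float = 16.0,
) -> float:
    """Fraction of single-copy reference genes whose primary fragment
    overlaps a same-orthogroup gene in every species with an annotated
    ortholog."""
    ref = dataset.reference
    others = [sp for sp in dataset.species if sp != ref]
    ok = 0
    for gid in single_copy_genes:
        region = resolve_query(gid, dataset.annotations[ref], dataset.genomes[ref], ref)
        og = dataset.orthogroups.og_of(gid)
        concordant = True
        for sp in others:
            members = set(dataset.orthogroups.members(og).get(sp, [])) if og else set()
            if not members:
                continue
            records = records_for_query(dataset.alignments.get(sp, []), region)
            fragments = assemble_fragments(records, gap_value, species=sp)
            retained, _ = filter_fragments(fragments, region.length, filtering_pct)
            fset = classify_fragments(retained, dataset.annotations.get(sp, []), species=sp)
            if fset.primary is None:
                concordant = False
                break
            hit = {g.gene_id for g in overlapping_genes(fset.primary, dataset.annotations[sp])}
            if not (hit & members):
                concordant = False
                break
        ok += concordant
    return ok / len(single_copy_genes) if single_copy_genes else 1.0
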