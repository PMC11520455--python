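"""Coordinate-level simulator of a small clade with known ground truth.

The simulator evolves a set of ancestral genes down a species guide tree,
applying substitutions (counted, never materialized as sequence), small
indels, whole-gene duplications (tandem or dispersed), inversions, intron
expansions, gene losses and annotation gaps.  It then emulates the output
of a liftover step over a multi-genome alignment: per-species PSL files
against the reference genome plus pairwise PSL files for display-adjacent
species, fragmented at every simulated indel so that downstream gap-based
assembly has real work to do.  Everything the pipeline consumes (PSL,
GFF3, orthogroup TSV, newick, mutation-event TSV) is emitted alongside a
ground-truth map: the true ortholog/paralog sets, duplication epochs,
parent/daughter identities, loss events and annotation gaps.

Sequence content is never materialized: alignment match/mismatch counts
are derived from simulated substitution counts, which keeps fixtures tiny
and exactly self-consistent.

Alignability model: liftover only recovers alignments that the underlying
whole-genome aligner found.  Alignable fraction decays with divergence, so
each emitted fragment is retained with probability 1 while the pairwise
per-base divergence d is below a threshold ``alignability_d0`` and with
probability exp(-alpha * (d - d0)) above it.  Orthologs of closely related
species therefore align fully, while fast-evolving daughter copies of
recent duplications lose part of their alignment — which is what makes
synteny depth rank ancient duplicates above single-copy genes above
recent duplicates, as observed in real clade alignments.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .formats import (
    Dataset,
    GeneModel,
    OrthogroupTable,
    PslRecord,
    SpeciesTree,
    parse_tree,
    write_gff3,
    write_orthogroups,
    write_psl,
)

DEFAULT_TREE = "((spA:0.4,spB:0.4):0.3,(spC:0.5,(spD:0.3,spE:0.3):0.2):0.2);"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic clade.

    Rates are per base per unit branch length unless stated otherwise;
    probabilities are per gene copy per branch.  The defaults define the
    golden fixture: 5 species, 100 genes, seed 42.
    """

    seed: int = 42
    tree: str = DEFAULT_TREE
    reference: str = "spA"
    n_genes: int = 100
    # gene geometry (bp)
    n_exons_range: tuple[int, int] = (2, 5)
    exon_len_range: tuple[int, int] = (150, 450)
    intron_len_range: tuple[int, int] = (80, 350)
    utr5_len: int = 60
    utr3_len: int = 90
    spacer_range: tuple[int, int] = (1500, 3500)
    flank: int = 2000
    # evolution
    sub_rate: float = 0.04
    indel_rate: float = 0.0012
    indel_size_range: tuple[int, int] = (5, 60)
    inversion_prob: float = 0.02
    intron_expansion_prob: float = 0.03
    intron_expansion_size: tuple[int, int] = (100, 400)
    loss_prob: float = 0.012
    annotation_gap_prob: float = 0.012
    dup_rate: float = 0.0
    tandem_fraction: float = 0.7
    # engineered duplication classes (counts of founder genes)
    n_ancient_dups: int = 6
    n_old_dups: int = 4
    n_recent_dups: int = 6
    daughter_burst_div: float = 0.25
    daughter_rate_multiplier: float = 3.0
    # liftover emulation
    min_block: int = 15
    alignability_d0: float = 0.15
    alignability_alpha: float = 10.0
    # per-node overrides, e.g. {"spB": {"dup_rate": 0.05}}
    rate_overrides: Mapping[str, Mapping[str, float]] = dc_field(default_factory=dict)

    def rate(self, name: str, node_label: str) -> float:
        return float(self.rate_overrides.get(node_label, {}).get(name, getattr(self, name)))

    @classmethod
    def null(cls, **kw) -> "SimConfig":
        """All rates zero: every species is an exact copy of the ancestor."""
        zeros = dict(
            sub_rate=0.0, indel_rate=0.0, inversion_prob=0.0,
            intron_expansion_prob=0.0, loss_prob=0.0, annotation_gap_prob=0.0,
            dup_rate=0.0, n_ancient_dups=0, n_old_dups=0, n_recent_dups=0,
        )
        zeros.update(kw)
        return cls(**zeros)


# ---------------------------------------------------------------------------
# ancestral genes and gene copies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AncGene:
    gene_id: str
    og: str
    length: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...]
    utr3: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...]


class Copy:
    """One gene copy in one genome, tracked in ancestral-gene coordinates.

    ``dels``/``ins`` are cumulative indels relative to the ancestral gene;
    ``subs_new`` counts substitutions gained since ``parent``; divergence
    between two copies is summed along their copy-genealogy paths to their
    lowest common ancestor copy.
    """

    __slots__ = (
        "anc", "label", "parent", "subs_new", "dels", "ins",
        "orientation", "origin", "dup_node", "daughter_lineage", "annotated",
    )

    def __init__(self, anc, label, parent, subs_new, dels, ins, orientation,
                 origin, dup_node, daughter_lineage):
        self.anc = anc
        self.label = label
        self.parent = parent
        self.subs_new = subs_new
        self.dels = dels
        self.ins = ins
        self.orientation = orientation
        self.origin = origin
        self.dup_node = dup_node
        self.daughter_lineage = daughter_lineage
        self.annotated = True

    @property
    def og(self) -> str:
        return self.anc.og


def pair_subs(x: Copy, y: Copy) -> int:
    """Substitutions separating two copies of the same founder gene."""
    chain_y = {}
    c, acc = y, 0
    while c is not None:
        chain_y[id(c)] = acc
        acc += c.subs_new
        c = c.parent
    c, acc = x, 0
    while c is not None:
        if id(c) in chain_y:
            return acc + chain_y[id(c)]
        acc += c.subs_new
        c = c.parent
    raise ValueError("copies do not share a founder")


# ---------------------------------------------------------------------------
# coordinate maps (ancestral <-> copy-local)
# ---------------------------------------------------------------------------


def survival_runs(anc_len: int, dels: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    runs, a = [], 0
    for p, s in sorted(dels):
        if p > a:
            runs.append((a, p))
        a = max(a, p + s)
    if a < anc_len:
        runs.append((a, anc_len))
    return runs


def coord_segments(
    anc_len: int,
    dels: Sequence[tuple[int, int]],
    ins: Sequence[tuple[int, int]],
) -> tuple[list[tuple[int, int, int]], int]:
    """Monotone map ancestral -> copy-local as (anc0, anc1, local0) segments.

    Returns the segments and the copy's local length.  Deletions remove
    ancestral intervals; insertions add local bases at an ancestral point.
    """
    runs = survival_runs(anc_len, dels)
    ins_sorted = sorted(ins)
    segs: list[tuple[int, int, int]] = []
    local, ii = 0, 0
    for r0, r1 in runs:
        while ii < len(ins_sorted) and ins_sorted[ii][0] <= r0:
            local += ins_sorted[ii][1]
            ii += 1
        cur = r0
        while ii < len(ins_sorted) and cur < ins_sorted[ii][0] < r1:
            p, s = ins_sorted[ii]
            if p > cur:
                segs.append((cur, p, local))
                local += p - cur
            local += s
            cur = p
            ii += 1
        if r1 > cur:
            segs.append((cur, r1, local))
            local += r1 - cur
    while ii < len(ins_sorted):
        local += ins_sorted[ii][1]
        ii += 1
    return segs, local


def map_interval(
    segs: Sequence[tuple[int, int, int]], a0: int, a1: int
) -> tuple[int, int] | None:
    """Hull of the copy-local image of an ancestral interval (None if lost)."""
    lo = hi = None
    for s0, s1, l0 in segs:
        if s1 <= a0 or s0 >= a1:
            continue
        x0, x1 = max(s0, a0), min(s1, a1)
        ll, lh = l0 + (x0 - s0), l0 + (x1 - s0)
        lo = ll if lo is None else min(lo, ll)
        hi = lh if hi is None else max(hi, lh)
    return None if lo is None else (lo, hi)


@dataclass(frozen=True)
class Placement:
    """A copy laid out on a species chromosome."""

    copy: Copy
    species: str
    chrom: str
    chrom_len: int
    offset: int
    segs: tuple[tuple[int, int, int], ...]
    local_len: int

    def to_genome(self, l0: int, l1: int) -> tuple[int, int]:
        if self.copy.orientation > 0:
            return (self.offset + l0, self.offset + l1)
        return (self.offset + self.local_len - l1, self.offset + self.local_len - l0)


# ---------------------------------------------------------------------------
# liftover emulation
# ---------------------------------------------------------------------------


def _alignability(d: float, cfg: SimConfig) -> float:
    if d <= cfg.alignability_d0:
        return 1.0
    return math.exp(-cfg.alignability_alpha * (d - cfg.alignability_d0))


def fragment_alignments(
    qp: Placement,
    tp: Placement,
    subs: int,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[PslRecord]:
    """Emit the fragmented PSL records of one true copy-vs-copy homology.

    The true alignment is broken at every indel present in either copy, so
    consecutive records are separated by target-side gaps equal to the
    simulated indel sizes (insertions in the target, deletions in the
    query).  Fragments shorter than ``min_block`` are dropped, and above
    the alignability divergence threshold whole fragments are lost at the
    rate the alignability model dictates.
    """
    # intersect the two monotone maps on the ancestral axis
    pieces: list[tuple[int, int, int, int]] = []  # a0, a1, qlocal0, tlocal0
    for qa0, qa1, ql0 in qp.segs:
        for ta0, ta1, tl0 in tp.segs:
            a0, a1 = max(qa0, ta0), min(qa1, ta1)
            if a1 <= a0:
                continue
            pieces.append((a0, a1, ql0 + (a0 - qa0), tl0 + (a0 - ta0)))
    pieces.sort()
    if not pieces:
        return []
    # group contiguous pieces (no gap on either side) into single fragments
    cur = list(pieces[0])
    frags: list[tuple[int, int, int]] = []
    for a0, a1, ql, tl in pieces[1:]:
        contig = ql == cur[2] + (cur[1] - cur[0]) and tl == cur[3] + (cur[1] - cur[0])
        if contig:
            cur[1] = a1
        else:
            frags.append((cur[2], cur[3], cur[1] - cur[0]))
            cur = [a0, a1, ql, tl]
    frags.append((cur[2], cur[3], cur[1] - cur[0]))
    alignable = sum(m for _, _, m in frags)
    d = subs / alignable if alignable else 0.0
    keep_p = _alignability(d, cfg)
    if keep_p < 1.0 and rng is not None:
        # above the alignability threshold the aligner recovers only
        # patches of each fragment: drop ~tile-sized pieces independently
        # and keep the merged runs of surviving tiles
        tile = 120
        patched: list[tuple[int, int, int]] = []
        for ql, tl, m in frags:
            run_start = None
            pos = 0
            while pos < m:
                step = min(tile, m - pos)
                if rng.random() < keep_p:
                    if run_start is None:
                        run_start = pos
                else:
                    if run_start is not None:
                        patched.append((ql + run_start, tl + run_start, pos - run_start))
                    run_start = None
                pos += step
            if run_start is not None:
                patched.append((ql + run_start, tl + run_start, m - run_start))
        if not any(m >= cfg.min_block for _, _, m in patched):
            # the best-conserved patch always stays alignable: anchor one
            # tile in the middle of the longest true fragment
            candidates = [f for f in frags if f[2] >= cfg.min_block]
            if candidates:
                ql, tl, m = max(candidates, key=lambda f: f[2])
                mid = max(0, (m - tile) // 2)
                patched.append((ql + mid, tl + mid, min(tile, m - mid)))
        frags = patched
    strand = "+" if qp.copy.orientation == tp.copy.orientation else "-"
    records: list[PslRecord] = []
    for ql, tl, m in frags:
        if m < cfg.min_block:
            continue
        fq0, fq1 = qp.to_genome(ql, ql + m)
        ft0, ft1 = tp.to_genome(tl, tl + m)
        mis = min(m, int(round(d * m)))
        if strand == "+":
            qstarts = (fq0,)
        else:
            qstarts = (qp.chrom_len - fq1,)
        rec = PslRecord(
            matches=m - mis, misMatches=mis, repMatches=0, nCount=0,
            qNumInsert=0, qBaseInsert=0, tNumInsert=0, tBaseInsert=0,
            strand=strand, qName=qp.chrom, qSize=qp.chrom_len,
            qStart=fq0, qEnd=fq1,
            tName=tp.chrom, tSize=tp.chrom_len, tStart=ft0, tEnd=ft1,
            blockCount=1, blockSizes=(m,), qStarts=qstarts, tStarts=(ft0,),
        )
        rec.validate("simulated record")
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# the simulation proper
# ---------------------------------------------------------------------------


@dataclass
class SyntheticClade:
    """Simulated genomes, emitted fixture files and the ground-truth map."""

    config: SimConfig
    tree: SpeciesTree
    reference: str
    genomes: dict[str, dict[str, int]]
    annotations: dict[str, list[GeneModel]]
    orthogroups: OrthogroupTable
    alignments: dict[str, list[PslRecord]]
    pairwise: dict[tuple[str, str], list[PslRecord]]
    dup_events: list[tuple[str, str, int]]  # node label, class, size
    truth: dict

    # duck-typed like formats.Dataset so analyses can run without disk I/O
    @property
    def species(self) -> list[str]:
        return self.tree.display_order

    def genes_by_id(self, species: str) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.annotations.get(species, [])}

    def write(self, out_dir: str | os.PathLike) -> Path:
        root = Path(out_dir)
        root.mkdir(parents=True, exist_ok=True)
        (root / "tree.nwk").write_text(self.config.tree.strip() + "\n")
        (root / "reference.txt").write_text(self.reference + "\n")
        lines = ["species\tseq_id\tlength"]
        for sp in self.tree.display_order:
            for seq, length in self.genomes[sp].items():
                lines.append(f"{sp}\t{seq}\t{length}")
        (root / "genomes.tsv").write_text("\n".join(lines) + "\n")
        (root / "annotations").mkdir(exist_ok=True)
        for sp, models in self.annotations.items():
            (root / "annotations" / f"{sp}.gff3").write_text(write_gff3(models))
        (root / "orthogroups.tsv").write_text(
            write_orthogroups(self.orthogroups, self.tree.display_order)
        )
        (root / "psl").mkdir(exist_ok=True)
        for sp, records in self.alignments.items():
            (root / "psl" / f"{self.reference}_vs_{sp}.psl").write_text(write_psl(records))
        (root / "psl_pairs").mkdir(exist_ok=True)
        for (a, b), records in self.pairwise.items():
            (root / "psl_pairs" / f"{a}__{b}.psl").write_text(write_psl(records))
        ev = ["species\tclass\tsize"]
        for node, cls, size in self.dup_events:
            ev.append(f"{node}\t{cls}\t{size}")
        (root / "dup_events.tsv").write_text("\n".join(ev) + "\n")
        (root / "truth.json").write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return root


def _make_anc_genes(cfg: SimConfig, rng: np.random.Generator) -> list[AncGene]:
    genes = []
    for i in range(cfg.n_genes):
        n_ex = int(rng.integers(cfg.n_exons_range[0], cfg.n_exons_range[1] + 1))
        exon_lens = rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1, n_ex)
        intron_lens = rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1,
                                   max(0, n_ex - 1))
        exons, introns = [], []
        pos = 0
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < len(intron_lens):
                introns.append((pos, pos + int(intron_lens[j])))
                pos += int(intron_lens[j])
        length = pos
        # transcript-order split into 5'UTR / CDS / 3'UTR
        utr5, utr3, cds = [], [], []
        t = 0
        total_ex = sum(e - s for s, e in exons)
        for s, e in exons:
            for lo, hi, bucket in (
                (0, cfg.utr5_len, utr5),
                (cfg.utr5_len, total_ex - cfg.utr3_len, cds),
                (total_ex - cfg.utr3_len, total_ex, utr3),
            ):
                x0, x1 = max(t, lo), min(t + (e - s), hi)
                if x1 > x0:
                    bucket.append((s + (x0 - t), s + (x1 - t)))
            t += e - s
        gid = f"g{i + 1:03d}"
        genes.append(
            AncGene(
                gene_id=gid, og=f"OG{i + 1:04d}", length=length,
                exons=tuple(exons), cds=tuple(cds), utr5=tuple(utr5),
                utr3=tuple(utr3), introns=tuple(introns),
            )
        )
    return genes


def _draw_indels(
    copy_dels: list, copy_ins: list, anc: AncGene, n: int,
    size_range: tuple[int, int], cfg: SimConfig, rng: np.random.Generator,
    intron_only: bool = False,
) -> int:
    """Draw up to n indels respecting minimum separations; returns max size."""
    min_sep = cfg.min_block + 10
    boundaries = [p for p, s in copy_dels] + [p + s for p, s in copy_dels] + \
                 [p for p, s in copy_ins]
    max_size = 0
    for _ in range(n):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        kind = "ins" if (intron_only or rng.random() < 0.5) else "del"
        placed = False
        for _attempt in range(20):
            if intron_only:
                if not anc.introns:
                    break
                i0, i1 = anc.introns[int(rng.integers(len(anc.introns)))]
                if i1 - i0 <= 2 * min_sep:
                    continue
                p = int(rng.integers(i0 + min_sep, i1 - min_sep))
            else:
                if anc.length <= 2 * min_sep + size:
                    break
                p = int(rng.integers(min_sep, anc.length - min_sep - size))
            span_hi = p + size if kind == "del" else p
            if any(abs(p - b) < min_sep or abs(span_hi - b) < min_sep for b in boundaries):
                continue
            if kind == "del" and any(
                p < dp + ds + min_sep and dp < span_hi + min_sep for dp, ds in copy_dels
            ):
                continue
            if kind == "del":
                copy_dels.append((p, size))
            else:
                copy_ins.append((p, size))
            boundaries.extend([p, span_hi])
            max_size = max(max_size, size)
            placed = True
            break
        if not placed:
            continue
    return max_size


def simulate_clade(config: SimConfig) -> SyntheticClade:
    """Run the simulation; deterministic for a fixed config."""
    cfg = config
    if cfg.n_genes <= 0:
        raise ValueError("n_genes must be > 0: configuration produces empty genomes")
    rng = np.random.default_rng(cfg.seed)
    rng_emit = np.random.default_rng(cfg.seed + 1_000_003)

    tree = parse_tree(cfg.tree)
    leaves = tree.display_order
    if cfg.reference not in leaves:
        raise ValueError(f"reference {cfg.reference!r} not a leaf of the tree")

    # label internal nodes deterministically (preorder)
    counter = [0]
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            node.sim_label = node.taxon.label
        elif node.parent_node is None:
            node.sim_label = "root"
        else:
            counter[0] += 1
            node.sim_label = f"n{counter[0]}"
    ref_leaf = next(
        n for n in tree.tree.leaf_node_iter() if n.taxon.label == cfg.reference
    )
    ref_path_labels = set()
    node = ref_leaf
    while node is not None:
        ref_path_labels.add(node.sim_label)
        node = node.parent_node
    ref_parent_label = ref_leaf.parent_node.sim_label if ref_leaf.parent_node else "root"

    anc_genes = _make_anc_genes(cfg, rng)

    # engineered duplication classes on disjoint founder sets
    n_forced = cfg.n_ancient_dups + cfg.n_old_dups + cfg.n_recent_dups
    if n_forced > cfg.n_genes:
        raise ValueError("more engineered duplications than genes")
    forced_idx = rng.choice(cfg.n_genes, size=n_forced, replace=False)
    ancient_ogs = {anc_genes[i].og for i in forced_idx[: cfg.n_ancient_dups]}
    old_ogs = {
        anc_genes[i].og
        for i in forced_idx[cfg.n_ancient_dups : cfg.n_ancient_dups + cfg.n_old_dups]
    }
    recent_ogs = {anc_genes[i].og for i in forced_idx[cfg.n_ancient_dups + cfg.n_old_dups :]}
    forced_at: dict[str, set[str]] = {
        ref_parent_label: old_ogs,
        cfg.reference: recent_ogs,
    }

    # event registries
    dup_registry: dict[str, list[str]] = {}  # og -> node labels of duplications
    loss_events: list[tuple[str, str]] = []  # (node label, og)
    dup_events: list[tuple[str, str, int]] = []
    max_indel = [0]

    def local_len(c: Copy) -> int:
        return coord_segments(c.anc.length, c.dels, c.ins)[1]

    def make_daughter(parent_copy: Copy, node_label: str) -> Copy:
        burst = int(rng.poisson(cfg.daughter_burst_div * parent_copy.anc.length))
        d = Copy(
            anc=parent_copy.anc,
            label=parent_copy.label + "b",
            parent=parent_copy,
            subs_new=burst,
            dels=tuple(parent_copy.dels),
            ins=tuple(parent_copy.ins),
            orientation=parent_copy.orientation,
            origin="daughter",
            dup_node=node_label,
            daughter_lineage=True,
        )
        dup_registry.setdefault(parent_copy.og, []).append(node_label)
        dup_events.append((node_label, "duplication", local_len(d)))
        return d

    # root genome: one ortholog copy per founder, plus ancient duplicates
    root_genome: list[Copy] = []
    for g in anc_genes:
        c = Copy(g, g.gene_id, None, 0, (), (), +1, "ortholog", None, False)
        root_genome.append(c)
        if g.og in ancient_ogs:
            daughter = make_daughter(c, "root")
            if rng.random() < cfg.tandem_fraction:
                root_genome.append(daughter)
            else:
                root_genome.insert(int(rng.integers(len(root_genome) + 1)), daughter)

    loss_pool = {
        g.og
        for g in anc_genes
        if g.og not in ancient_ogs | old_ogs | recent_ogs
    }

    # losses and annotation gaps per orthogroup are capped so that at least
    # one non-reference species keeps an annotated member: an orthogroup
    # surviving only in the reference cannot anchor cross-species queries
    leaves_under = {
        n.sim_label: {lf.taxon.label for lf in n.leaf_iter()}
        for n in tree.tree.preorder_node_iter()
    }
    og_affected: dict[str, set[str]] = {}
    max_affected = len(leaves) - 2  # all non-reference leaves but one

    def event_allowed(og: str, leaf_set: set[str]) -> bool:
        combined = og_affected.get(og, set()) | leaf_set
        if len(combined) > max_affected:
            return False
        og_affected[og] = combined
        return True

    leaf_genomes: dict[str, list[Copy]] = {}

    def evolve(node, genome: list[Copy]) -> None:
        if node.is_leaf():
            leaf_genomes[node.sim_label] = genome
            return
        for child in node.child_nodes():
            b = child.edge.length or 0.0
            label = child.sim_label
            new_genome: list[Copy] = []
            dispersed: list[Copy] = []
            for c in genome:
                if (
                    c.og in loss_pool
                    and label not in ref_path_labels
                    and rng.random() < cfg.rate("loss_prob", label)
                    and event_allowed(c.og, leaves_under[label])
                ):
                    loss_events.append((label, c.og))
                    continue
                mult = cfg.daughter_rate_multiplier if c.daughter_lineage else 1.0
                subs = int(rng.poisson(cfg.rate("sub_rate", label) * mult * b * c.anc.length))
                dels = list(c.dels)
                ins = list(c.ins)
                n_indels = int(
                    rng.poisson(cfg.rate("indel_rate", label) * mult * b * c.anc.length)
                )
                mx = _draw_indels(dels, ins, c.anc, n_indels, cfg.indel_size_range, cfg, rng)
                max_indel[0] = max(max_indel[0], mx)
                if rng.random() < cfg.rate("intron_expansion_prob", label):
                    mx = _draw_indels(
                        dels, ins, c.anc, 1, cfg.intron_expansion_size, cfg, rng,
                        intron_only=True,
                    )
                    max_indel[0] = max(max_indel[0], mx)
                orientation = c.orientation
                if rng.random() < cfg.rate("inversion_prob", label):
                    orientation = -orientation
                # the elevated daughter rate applies only on the first branch
                # after the duplication; afterwards the copy evolves normally
                child_copy = Copy(
                    anc=c.anc, label=c.label, parent=c, subs_new=subs,
                    dels=tuple(sorted(dels)), ins=tuple(sorted(ins)),
                    orientation=orientation, origin=c.origin,
                    dup_node=c.dup_node, daughter_lineage=False,
                )
                new_genome.append(child_copy)
                do_forced = (
                    c.origin == "ortholog" and c.og in forced_at.get(label, ())
                )
                if do_forced or (
                    cfg.dup_rate > 0 and rng.random() < cfg.rate("dup_rate", label)
                ):
                    daughter = make_daughter(child_copy, label)
                    if rng.random() < cfg.tandem_fraction:
                        new_genome.append(daughter)
                    else:
                        dispersed.append(daughter)
            for d in dispersed:
                new_genome.insert(int(rng.integers(len(new_genome) + 1)), d)
            if not new_genome:
                raise ValueError(f"all genes lost on branch to {label}")
            evolve(child, new_genome)

    evolve(tree.tree.seed_node, root_genome)

    # ---- layout, annotation gaps, GFF3 ----------------------------------
    placements: dict[str, dict[int, Placement]] = {}  # species -> id(copy) -> placement
    genomes: dict[str, dict[str, int]] = {}
    annotations: dict[str, list[GeneModel]] = {}
    gap_events: list[dict] = []
    expanded_losses: list[dict] = []

    for sp in leaves:
        genome = leaf_genomes[sp]
        rng_layout = np.random.default_rng((cfg.seed + 7919) % 2**31)
        chrom = f"{sp}_chr1"
        cursor = cfg.flank
        placed: list[tuple[Copy, int, tuple, int]] = []
        for c in genome:
            segs, llen = coord_segments(c.anc.length, c.dels, c.ins)
            placed.append((c, cursor, tuple(segs), llen))
            cursor += llen + int(rng_layout.integers(cfg.spacer_range[0], cfg.spacer_range[1] + 1))
        chrom_len = cursor + cfg.flank
        genomes[sp] = {chrom: chrom_len}
        placements[sp] = {}
        models = []
        for c, off, segs, llen in placed:
            pl = Placement(
                copy=c, species=sp, chrom=chrom, chrom_len=chrom_len,
                offset=off, segs=segs, local_len=llen,
            )
            placements[sp][id(c)] = pl
            # annotation-gap events: alignment stays, annotation (and OG
            # membership) disappears; restricted to never-duplicated genes
            # off the reference so truth matches what detection can see
            if (
                sp != cfg.reference
                and c.og in loss_pool
                and c.og not in dup_registry
                and rng_emit.random() < cfg.annotation_gap_prob
                and event_allowed(c.og, {sp})
            ):
                c.annotated = False
                g0, g1 = pl.to_genome(0, llen)
                gap_events.append(
                    {
                        "species": sp, "orthogroup": c.og,
                        "ref_gene": f"{cfg.reference}_{c.label}",
                        "seq": chrom, "interval": [g0, g1],
                    }
                )
                continue
            strand = "+" if c.orientation > 0 else "-"
            g0, g1 = pl.to_genome(0, llen)

            def mapped(ivs):
                out = []
                for a0, a1 in ivs:
                    m = map_interval(segs, a0, a1)
                    if m is not None:
                        out.append(pl.to_genome(m[0], m[1]))
                return sorted(out)

            models.append(
                GeneModel(
                    gene_id=f"{sp}_{c.label}", species=sp, seq_id=chrom,
                    start=g0, end=g1, strand=strand,
                    exons=mapped(c.anc.exons), cds=mapped(c.anc.cds),
                    utr5=mapped(c.anc.utr5), utr3=mapped(c.anc.utr3),
                    orthogroup_id=c.og,
                )
            )
        annotations[sp] = models

    # orthogroup table over annotated copies
    groups: dict[str, dict[str, list[str]]] = {}
    for sp in leaves:
        for c in leaf_genomes[sp]:
            if not c.annotated:
                continue
            groups.setdefault(c.og, {}).setdefault(sp, []).append(f"{sp}_{c.label}")
    for og in groups:
        for sp in leaves:
            groups[og].setdefault(sp, [])
    orthogroups = OrthogroupTable(groups)

    # ---- PSL emission ----------------------------------------------------
    ref = cfg.reference
    ref_genome = leaf_genomes[ref]
    by_og: dict[str, dict[str, list[Copy]]] = {}
    for sp in leaves:
        for c in leaf_genomes[sp]:
            by_og.setdefault(c.og, {}).setdefault(sp, []).append(c)

    single_copy_ogs = {
        og
        for og in by_og
        if og in loss_pool
        and og not in dup_registry
        and all(len(by_og[og].get(sp, [])) == 1 for sp in leaves)
        and not any(e["orthogroup"] == og for e in gap_events)
    }

    safe_gap = [1]
    alignments: dict[str, list[PslRecord]] = {}
    for sp in leaves:
        if sp == ref:
            continue
        records: list[PslRecord] = []
        for og, per_sp in by_og.items():
            for x in per_sp.get(ref, []):
                for y in per_sp.get(sp, []):
                    recs = fragment_alignments(
                        placements[ref][id(x)], placements[sp][id(y)],
                        pair_subs(x, y), cfg, rng_emit,
                    )
                    if og in single_copy_ogs and recs:
                        recs_sorted = sorted(recs, key=lambda r: r.tStart)
                        for r1, r2 in zip(recs_sorted, recs_sorted[1:]):
                            safe_gap[0] = max(safe_gap[0], r2.tStart - r1.tEnd)
                    records.extend(recs)
        records.sort(key=lambda r: (r.qName, r.qStart, r.tName, r.tStart))
        alignments[sp] = records

    pairwise: dict[tuple[str, str], list[PslRecord]] = {}
    for a, b in tree.adjacent_pairs():
        records = []
        for og, per_sp in by_og.items():
            for x in per_sp.get(a, []):
                for y in per_sp.get(b, []):
                    records.extend(
                        fragment_alignments(
                            placements[a][id(x)], placements[b][id(y)],
                            pair_subs(x, y), cfg, rng_emit,
                        )
                    )
        records.sort(key=lambda r: (r.qName, r.qStart, r.tName, r.tStart))
        pairwise[(a, b)] = records

    # indel/deletion bookkeeping rows for the mutation-event table
    for node_label, og in loss_events:
        dup_events.append((node_label, "gene_loss", next(
            g.length for g in anc_genes if g.og == og
        )))

    # ---- ground truth ----------------------------------------------------
    def ref_gene_ids(og: str) -> list[str]:
        return [f"{ref}_{c.label}" for c in by_og.get(og, {}).get(ref, [])]

    classes: dict[str, list[str]] = {
        "single_copy": [], "recent": [], "old": [], "ancient": [], "other": [],
    }
    for g in anc_genes:
        og = g.og
        ids = ref_gene_ids(og)
        dups = dup_registry.get(og, [])
        losses = [e for e in loss_events if e[1] == og]
        gaps = [e for e in gap_events if e["orthogroup"] == og]
        if og in single_copy_ogs:
            classes["single_copy"].extend(ids)
        elif len(dups) == 1 and not losses and not gaps and len(ids) == 2:
            node_label = dups[0]
            if node_label == "root":
                classes["ancient"].extend(ids)
            elif node_label == ref:
                classes["recent"].extend(ids)
            elif node_label in ref_path_labels:
                classes["old"].extend(ids)
            else:
                classes["other"].extend(ids)
        else:
            classes["other"].extend(ids)

    # expand losses to affected leaves
    label_to_node = {n.sim_label: n for n in tree.tree.preorder_node_iter()}
    for node_label, og in loss_events:
        for leaf in label_to_node[node_label].leaf_iter():
            expanded_losses.append(
                {
                    "species": leaf.taxon.label,
                    "orthogroup": og,
                    "ref_gene": (ref_gene_ids(og) or [""])[0],
                }
            )

    parent_daughter = []
    for og in recent_ogs:
        copies = by_og.get(og, {}).get(ref, [])
        parents = [c for c in copies if c.origin == "ortholog"]
        daughters = [c for c in copies if c.origin == "daughter"]
        if len(parents) == 1 and len(daughters) == 1:
            parent_daughter.append(
                {
                    "orthogroup": og,
                    "parent": f"{ref}_{parents[0].label}",
                    "daughter": f"{ref}_{daughters[0].label}",
                }
            )

    truth = {
        "reference": ref,
        "n_species": len(leaves),
        "max_indel": max_indel[0],
        "assembly_safe_gap": safe_gap[0],
        "gene_classes": classes,
        "losses": expanded_losses,
        "annotation_gaps": gap_events,
        "parent_daughter": parent_daughter,
        "single_copy_orthogroups": sorted(single_copy_ogs),
    }

    return SyntheticClade(
        config=cfg, tree=tree, reference=ref, genomes=genomes,
        annotations=annotations, orthogroups=orthogroups,
        alignments=alignments, pairwise=pairwise,
        dup_events=dup_events, truth=truth,
    )


def simulate_dataset(config: SimConfig, out_dir: str | os.PathLike) -> Dataset:
    """Simulate, write the fixture bundle to disk, and load it back."""
    clade = simulate_clade(config)
    root = clade.write(out_dir)
    return Dataset.load(root)
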