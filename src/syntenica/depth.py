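"""Genome-wide synteny depth over the reference genome.

Synteny depth at a reference base is the number of alignment blocks — from
all other species, counting paralogous alignments separately — that cover
the base.  Depth is summarized per non-overlapping window (default 20 kb),
per feature class (CDS-bearing exon, 5'UTR, 3'UTR, intron, intergenic) and
per gene class (single-copy vs. duplicates of different ages), mirroring
how genome-wide conservation is usually surveyed in clade alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats import GeneModel, PslRecord

FEATURE_CLASSES = ("exon", "utr5", "utr3", "intron", "intergenic")

# per-base classification codes, higher wins (precedence exon > 5'UTR >
# 3'UTR > intron > intergenic)
_CODE = {"intergenic": 0, "intron": 1, "utr3": 2, "utr5": 3, "exon": 4}


@dataclass
class DepthProfile:
    """Per-base alignment coverage over each reference sequence."""

    depth: dict[str, np.ndarray]
    species: list[str] = field(default_factory=list)
    aligned_bases_per_species: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return int(sum(int(v.sum()) for v in self.depth.values()))

    def mean(self) -> float:
        n = sum(len(v) for v in self.depth.values())
        return self.total() / n if n else 0.0


@dataclass(frozen=True)
class WindowSummary:
    seq_id: str
    window_start: int
    window_end: int
    mean_depth: float
    window_size: int


def depth_profile(
    alignments: Mapping[str, Sequence[PslRecord]],
    sequence_lengths: Mapping[str, int],
) -> DepthProfile:
    """Accumulate per-base block coverage on the reference (query) side.

    ``alignments`` maps each non-reference species to its liftover PSL
    records with the reference genome as query.  Every block of every
    record contributes, so paralogous alignments count multiply.
    """
    depth = {seq: np.zeros(length, dtype=np.int32) for seq, length in sequence_lengths.items()}
    per_species: dict[str, int] = {}
    for sp, records in alignments.items():
        total = 0
        for r in records:
            if r.qName not in depth:
                raise ValueError(f"record query sequence {r.qName!r} has no declared length")
            vec = depth[r.qName]
            for s, e in r.query_blocks():
                if e > len(vec):
                    raise ValueError(
                        f"block [{s},{e}) outside declared length of {r.qName} ({len(vec)})"
                    )
                vec[s:e] += 1
                total += e - s
        per_species[sp] = total
    return DepthProfile(
        depth=depth, species=sorted(alignments), aligned_bases_per_species=per_species
    )


def window_means(profile: DepthProfile, window: int = 20_000) -> list[WindowSummary]:
    """Mean depth per non-overlapping tiling window.

    A trailing partial window is averaged over its actual width.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    out: list[WindowSummary] = []
    for seq in sorted(profile.depth):
        vec = profile.depth[seq]
        for start in range(0, len(vec), window):
            chunk = vec[start : start + window]
            out.append(
                WindowSummary(
                    seq_id=seq,
                    window_start=start,
                    window_end=start + len(chunk),
                    mean_depth=float(chunk.mean()),
                    window_size=window,
                )
            )
    return out


def classify_bases(
    genes: Iterable[GeneModel], sequence_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Per-base feature-class codes with exon > 5'UTR > 3'UTR > intron
    > intergenic precedence (applied per base when genes overlap)."""
    codes = {seq: np.zeros(length, dtype=np.int8) for seq, length in sequence_lengths.items()}
    for g in genes:
        vec = codes.get(g.seq_id)
        if vec is None:
            continue
        np.maximum(vec[g.start : g.end], _CODE["intron"], out=vec[g.start : g.end])
        for cls, ivs in (("utr3", g.utr3), ("utr5", g.utr5), ("exon", g.cds)):
            for s, e in ivs:
                np.maximum(vec[s:e], _CODE[cls], out=vec[s:e])
    return codes


def feature_class_depth(
    profile: DepthProfile,
    genes: Sequence[GeneModel],
    sequence_lengths: Mapping[str, int],
) -> dict[str, list[float]]:
    """Mean depth per gene (or per intergenic block) for each feature class.

    "exon" means CDS-bearing exonic bases; UTR bases form their own
    classes.  For each gene, the mean depth over its bases of a given class
    is one observation of that class' distribution; intergenic observations
    are the means over maximal intergenic blocks.
    """
    codes = classify_bases(genes, sequence_lengths)
    dists: dict[str, list[float]] = {cls: [] for cls in FEATURE_CLASSES}
    for g in genes:
        vec = profile.depth.get(g.seq_id)
        cvec = codes.get(g.seq_id)
        if vec is None:
            continue
        span_codes = cvec[g.start : g.end]
        span_depth = vec[g.start : g.end]
        for cls in ("exon", "utr5", "utr3", "intron"):
            mask = span_codes == _CODE[cls]
            if mask.any():
                dists[cls].append(float(span_depth[mask].mean()))
    for seq in sorted(profile.depth):
        cvec = codes.get(seq)
        if cvec is None:
            continue
        inter = cvec == _CODE["intergenic"]
        # maximal runs of intergenic bases
        edges = np.flatnonzero(np.diff(np.concatenate(([0], inter.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            dists["intergenic"].append(float(profile.depth[seq][s:e].mean()))
    return dists


def gene_mean_depth(profile: DepthProfile, gene: GeneModel) -> float:
    vec = profile.depth.get(gene.seq_id)
    if vec is None:
        raise ValueError(f"no depth for sequence {gene.seq_id!r}")
    return float(vec[gene.start : gene.end].mean())


def gene_class_depth(
    profile: DepthProfile,
    genes: Sequence[GeneModel],
    gene_classes: Mapping[str, Iterable[str]],
) -> dict[str, list[float]]:
    """Mean depth over the gene body, grouped into the supplied classes
    (e.g. single-copy / recent / old / ancient duplicates / other)."""
    by_id = {g.gene_id: g for g in genes}
    out: dict[str, list[float]] = {}
    for cls, ids in gene_classes.items():
        vals = []
        for gid in ids:
            g = by_id.get(gid)
            if g is None:
                import logging

                logging.getLogger("syntenica").warning("unknown gene id %s; skipped", gid)
                continue
            vals.append(gene_mean_depth(profile, g))
        out[cls] = vals
    return out


def write_bedgraph(profile: DepthProfile) -> str:
    """Run-length encode the profile as BedGraph text."""
    lines = ["track type=bedGraph name=synteny_depth"]
    for seq in sorted(profile.depth):
        vec = profile.depth[seq]
        if len(vec) == 0:
            continue
        change = np.flatnonzero(np.diff(vec)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(vec)]))
        for s, e in zip(starts, ends):
            lines.append(f"{seq}\t{s}\t{e}\t{int(vec[s])}")
    return "\n".join(lines) + "\n"


def windows_table(windows: Sequence[WindowSummary]) -> str:
    lines = ["seq_id\twindow_start\twindow_end\tmean_depth"]
    for w in windows:
        lines.append(f"{w.seq_id}\t{w.window_start}\t{w.window_end}\t{w.mean_depth:.4f}")
    return "\n".join(lines) + "\n"


def class_table(dists: Mapping[str, Sequence[float]], value_name: str = "mean_depth") -> str:
    lines = [f"class\t{value_name}"]
    for cls in dists:
        for v in dists[cls]:
            lines.append(f"{cls}\t{v:.4f}")
    return "\n".join(lines) + "\n"
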