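"""Alignment (PSL) scoring of paralogs and parent/daughter inference.

When a duplication produced two paralogs that both align to the single
ortholog in other species, the copy retaining better alignments across the
clade is the likely parental (ancestral-position) gene.  The score of an
alignment is the classic PSL score

    score = matches + repMatches - misMatches - qNumInsert - tNumInsert

summed over the members of an assembled fragment and optionally normalized
to the paralog's length (reported per kb).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

from .assembly import AssembledFragment, assemble_fragments, records_for_query, QueryRegion
from .formats import Dataset, GeneModel, PslRecord


def psl_score(item: Union[PslRecord, AssembledFragment]) -> int:
    """matches + repMatches - misMatches - qNumInsert - tNumInsert."""
    if isinstance(item, AssembledFragment):
        return item.score()
    return item.matches + item.repMatches - item.misMatches - item.qNumInsert - item.tNumInsert


@dataclass(frozen=True)
class ParalogScore:
    """Score of one paralog's best assembled alignment in one partner species."""

    gene_id: str
    partner_species: str
    raw_score: int
    normalized_score: float  # raw score per kb of paralog length
    n_alignments: int


@dataclass
class ParentDaughterCall:
    """Outcome of comparing a paralog pair's alignment scores across species."""

    parent: str | None
    daughter: str | None
    mean_scores: dict[str, float]
    margin: float
    scores: list[ParalogScore] = field(default_factory=list)
    reason: str = ""

    @property
    def determined(self) -> bool:
        return self.parent is not None


def score_paralog(
    gene: GeneModel,
    dataset: Dataset,
    gap_value: int,
) -> list[ParalogScore]:
    """Best-fragment PSL score of ``gene`` against every partner species."""
    region = QueryRegion(gene.seq_id, gene.start, gene.end, gene.species, source=gene.gene_id)
    out: list[ParalogScore] = []
    for sp in dataset.species:
        if sp == dataset.reference:
            continue
        records = records_for_query(dataset.alignments.get(sp, []), region)
        fragments = assemble_fragments(records, gap_value, species=sp)
        if not fragments:
            continue
        best = max(fragments, key=lambda f: (f.score(), f.length))
        raw = best.score()
        out.append(
            ParalogScore(
                gene_id=gene.gene_id,
                partner_species=sp,
                raw_score=raw,
                normalized_score=raw / gene.length * 1000.0,
                n_alignments=len(best.members),
            )
        )
    return out


def infer_parent_daughter(
    gene_a: str,
    gene_b: str,
    dataset: Dataset,
    gap_value: int = 200,
    use_normalized: bool = True,
) -> ParentDaughterCall:
    """Infer which of two reference paralogs is the parental gene.

    Each paralog is scored against every other species; the paralog with
    the greater mean (normalized, by default) score is called the parent.
    Ties and paralogs with no alignment at all give an undetermined call.
    The call is invariant to the order of the pair.
    """
    ref_genes = dataset.genes_by_id(dataset.reference)
    calls: dict[str, list[ParalogScore]] = {}
    for gid in (gene_a, gene_b):
        if gid not in ref_genes:
            raise ValueError(f"gene {gid!r} not annotated in reference species")
        calls[gid] = score_paralog(ref_genes[gid], dataset, gap_value)
    all_scores = calls[gene_a] + calls[gene_b]
    key = "normalized_score" if use_normalized else "raw_score"
    means: dict[str, float] = {}
    for gid in (gene_a, gene_b):
        if not calls[gid]:
            return ParentDaughterCall(
                parent=None, daughter=None, mean_scores={}, margin=0.0,
                scores=all_scores, reason=f"{gid} has no alignment in any partner species",
            )
        means[gid] = sum(getattr(s, key) for s in calls[gid]) / len(calls[gid])
    if means[gene_a] == means[gene_b]:
        return ParentDaughterCall(
            parent=None, daughter=None, mean_scores=means, margin=0.0,
            scores=all_scores, reason="equal mean scores",
        )
    parent = max((gene_a, gene_b), key=lambda g: means[g])
    daughter = gene_b if parent == gene_a else gene_a
    return ParentDaughterCall(
        parent=parent, daughter=daughter, mean_scores=means,
        margin=abs(means[gene_a] - means[gene_b]), scores=all_scores,
    )


def scores_table(scores: Sequence[ParalogScore]) -> str:
    lines = ["gene\tspecies\traw\tnormalized_per_kb\tn_alignments"]
    for s in scores:
        lines.append(
            f"{s.gene_id}\t{s.partner_species}\t{s.raw_score}"
            f"\t{s.normalized_score:.3f}\t{s.n_alignments}"
        )
    return "\n".join(lines) + "\n"
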