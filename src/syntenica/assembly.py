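"""Assembly of liftover alignment fragments into synteny fragments.

Liftover of a query region through a multi-genome alignment returns many
small PSL records per target species, broken wherever the alignment has an
indel.  This module chains those records back into larger homologous
fragments under a user gap threshold (``gap_value``), drops fragments
shorter than a percentage of the query length (``filtering_pct``), and
classifies what is left into the primary fragment, co-gene fragments shown
with it, and secondary "(filtered)" fragments (typically paralogous hits).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .formats import GeneModel, PslRecord

AGGREGATE_KEYS = (
    "matches", "misMatches", "repMatches", "nCount",
    "qNumInsert", "qBaseInsert", "tNumInsert", "tBaseInsert",
)


@dataclass(frozen=True)
class QueryRegion:
    """The query: a reference-genome interval, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    species: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("query region must have positive length")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AssembledFragment:
    """A gap-merged chain of PSL records on one target sequence and strand."""

    target_species: str
    t_seq: str
    t_start: int
    t_end: int
    strand: str
    q_seq: str
    q_start: int
    q_end: int
    members: tuple[int, ...]  # indices into the record list passed to assemble
    aggregate: Mapping[str, int]
    aligned_bases: int

    @property
    def length(self) -> int:
        return self.t_end - self.t_start

    @property
    def t_span(self) -> tuple[int, int]:
        return (self.t_start, self.t_end)

    def score(self) -> int:
        a = self.aggregate
        return a["matches"] + a["repMatches"] - a["misMatches"] - a["qNumInsert"] - a["tNumInsert"]


@dataclass
class FragmentSet:
    """Classified fragments for one target species.

    ``primary`` is the longest retained fragment (shown on top), ``co_gene``
    are smaller retained fragments hitting the same gene(s) as the primary
    (also top panel), ``secondary`` are the remaining retained fragments
    (bottom panel, displayed with a "(filtered)" label), and ``discarded``
    fell below the length filter.
    """

    species: str
    primary: AssembledFragment | None = None
    co_gene: list[AssembledFragment] = field(default_factory=list)
    secondary: list[AssembledFragment] = field(default_factory=list)
    discarded: list[AssembledFragment] = field(default_factory=list)

    def displayed(self) -> list[AssembledFragment]:
        out = []
        if self.primary is not None:
            out.append(self.primary)
        out.extend(self.co_gene)
        out.extend(self.secondary)
        return out


def _fragment_from_chain(
    records: Sequence[PslRecord], chain: list[int], species: str
) -> AssembledFragment:
    members = tuple(chain)
    recs = [records[i] for i in chain]
    agg = {k: sum(getattr(r, k) for r in recs) for k in AGGREGATE_KEYS}
    q_lo = min(min(b[0] for b in r.query_blocks()) for r in recs)
    q_hi = max(max(b[1] for b in r.query_blocks()) for r in recs)
    return AssembledFragment(
        target_species=species,
        t_seq=recs[0].tName,
        t_start=min(r.tStart for r in recs),
        t_end=max(r.tEnd for r in recs),
        strand=recs[0].strand,
        q_seq=recs[0].qName,
        q_start=q_lo,
        q_end=q_hi,
        members=members,
        aggregate=agg,
        aligned_bases=sum(r.aligned_bases for r in recs),
    )


def assemble_fragments(
    records: Sequence[PslRecord], gap_value: int, species: str = ""
) -> list[AssembledFragment]:
    """Chain PSL records into assembled fragments under the gap threshold.

    Records are grouped by (target sequence, strand) and sorted by target
    start; a chain is extended while the next record starts within
    ``gap_value`` bp of the running end of the chain.  The gap is measured
    on target coordinates.  Output is sorted by descending fragment length.
    """
    if gap_value < 0:
        raise ValueError("gap_value must be >= 0")
    if not records:
        return []
    qnames = {r.qName for r in records}
    if len(qnames) > 1:
        raise ValueError(f"records span multiple query sequences: {sorted(qnames)}")
    groups: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(records):
        groups.setdefault((r.tName, r.strand), []).append(i)
    fragments: list[AssembledFragment] = []
    for key in sorted(groups):
        idx = sorted(groups[key], key=lambda i: (records[i].tStart, records[i].tEnd))
        chain = [idx[0]]
        chain_end = records[idx[0]].tEnd
        for i in idx[1:]:
            if records[i].tStart - chain_end <= gap_value:
                chain.append(i)
                chain_end = max(chain_end, records[i].tEnd)
            else:
                fragments.append(_fragment_from_chain(records, chain, species))
                chain = [i]
                chain_end = records[i].tEnd
        fragments.append(_fragment_from_chain(records, chain, species))
    fragments.sort(
        key=lambda f: (-f.length, -f.aggregate["matches"], f.t_seq, f.t_start, f.strand)
    )
    return fragments


def filter_fragments(
    fragments: Sequence[AssembledFragment], query_len: int, filtering_pct: float
) -> tuple[list[AssembledFragment], list[AssembledFragment]]:
    """Split fragments into (retained, discarded) by the length threshold.

    A fragment is retained iff its target-span length is at least
    ``filtering_pct``/100 of the query length (inclusive).
    """
    if query_len <= 0:
        raise ValueError("query_len must be > 0")
    threshold = filtering_pct / 100.0 * query_len
    retained = [f for f in fragments if f.length >= threshold]
    discarded = [f for f in fragments if f.length < threshold]
    return retained, discarded


def _gene_tree(genes: Iterable[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.seq_id, IntervalTree()).addi(g.start, g.end, g)
    return trees


def overlapping_genes(
    fragment: AssembledFragment, genes: Iterable[GeneModel] | dict[str, IntervalTree]
) -> list[GeneModel]:
    trees = genes if isinstance(genes, dict) else _gene_tree(genes)
    tree = trees.get(fragment.t_seq)
    if tree is None:
        return []
    hits = [iv.data for iv in tree.overlap(fragment.t_start, fragment.t_end)]
    hits.sort(key=lambda g: (g.start, g.gene_id))
    return hits


def classify_fragments(
    retained: Sequence[AssembledFragment],
    genes: Iterable[GeneModel],
    species: str = "",
    discarded: Sequence[AssembledFragment] = (),
) -> FragmentSet:
    """Classify one species' retained fragments into primary/co-gene/secondary.

    The primary is the longest retained fragment (ties: larger aggregate
    matches, then smaller target start).  Retained fragments whose span
    overlaps any gene that the primary overlaps are co-gene; the rest are
    secondary and displayed with a "(filtered)" label.
    """
    species = species or (retained[0].target_species if retained else "")
    fset = FragmentSet(species=species, discarded=list(discarded))
    if not retained:
        return fset
    trees = _gene_tree(genes)
    primary = min(
        retained, key=lambda f: (-f.length, -f.aggregate["matches"], f.t_seq, f.t_start)
    )
    fset.primary = primary
    primary_gene_ids = {g.gene_id for g in overlapping_genes(primary, trees)}
    for f in retained:
        if f is primary:
            continue
        hit_ids = {g.gene_id for g in overlapping_genes(f, trees)}
        if hit_ids & primary_gene_ids:
            fset.co_gene.append(f)
        else:
            fset.secondary.append(f)
    return fset


def full_gene_extension(
    fragment: AssembledFragment, genes: Iterable[GeneModel] | dict[str, IntervalTree]
) -> AssembledFragment:
    """Extend a fragment's target span to the full extent of the genes it hits.

    The span becomes the hull of the fragment and every overlapped gene,
    iterated to a fixpoint so the operation is idempotent.  Aggregates are
    unchanged; a fragment hitting no gene is returned as-is.
    """
    trees = genes if isinstance(genes, dict) else _gene_tree(genes)
    start, end = fragment.t_start, fragment.t_end
    while True:
        probe = replace(fragment, t_start=start, t_end=end)
        hits = overlapping_genes(probe, trees)
        if not hits:
            break
        new_start = min(start, min(g.start for g in hits))
        new_end = max(end, max(g.end for g in hits))
        if (new_start, new_end) == (start, end):
            break
        start, end = new_start, new_end
    if (start, end) == (fragment.t_start, fragment.t_end):
        return fragment
    return replace(fragment, t_start=start, t_end=end)


def resolve_query(
    query: str,
    annotations: Iterable[GeneModel],
    genome: Mapping[str, int],
    species: str,
) -> QueryRegion:
    """Resolve a gene name or a ``seq:start-end`` string to a query region.

    Coordinate strings are 1-based closed (``I:101-200`` or ``I:101..200``)
    as users type them; gene names resolve to the annotated gene span.
    """
    by_id = {g.gene_id: g for g in annotations}
    if query in by_id:
        g = by_id[query]
        return QueryRegion(g.seq_id, g.start, g.end, species, source=query)
    if ":" in query:
        seq_id, _, rng = query.partition(":")
        sep = ".." if ".." in rng else "-"
        parts = rng.replace(",", "").split(sep)
        try:
            start1, end1 = int(parts[0]), int(parts[1])
        except (ValueError, IndexError):
            raise ValueError(f"cannot parse coordinates {query!r}") from None
        if seq_id not in genome:
            raise ValueError(f"unknown sequence {seq_id!r} for species {species}")
        if start1 < 1 or end1 > genome[seq_id] or start1 > end1:
            raise ValueError(f"coordinates {query!r} out of range for {seq_id}")
        return QueryRegion(seq_id, start1 - 1, end1, species, source=query)
    raise ValueError(f"unknown gene {query!r} in {species} annotation")


def records_for_query(
    records: Iterable[PslRecord], region: QueryRegion
) -> list[PslRecord]:
    """Records whose forward query span overlaps the query region."""
    out = []
    for r in records:
        if r.qName != region.seq_id:
            continue
        if r.qStart < region.end and r.qEnd > region.start:
            out.append(r)
    return out


def fragments_table(fragment_sets: Mapping[str, FragmentSet]) -> str:
    """Flatten classified fragments to the TSV emitted by the CLI."""
    lines = [
        "species\tt_seq\tt_start\tt_end\tstrand\tlength\tn_members\tmatches\tclass"
    ]
    for sp, fset in fragment_sets.items():
        rows = [("primary", f) for f in ([fset.primary] if fset.primary else [])]
        rows += [("co_gene", f) for f in fset.co_gene]
        rows += [("secondary (filtered)", f) for f in fset.secondary]
        for cls, f in rows:
            lines.append(
                f"{sp}\t{f.t_seq}\t{f.t_start}\t{f.t_end}\t{f.strand}\t{f.length}"
                f"\t{len(f.members)}\t{f.aggregate['matches']}\t{cls}"
            )
    return "\n".join(lines) + "\n"
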