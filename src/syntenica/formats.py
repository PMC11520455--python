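"""Readers and writers for the external formats the pipeline touches.

The pipeline is coordinate-only: its atoms are PSL alignment records
(the 21-column BLAT dialect emitted by liftover tools), GFF3 gene models,
an orthogroup table, and a newick species guide tree.  All coordinates are
stored internally as 0-based half-open intervals; conversions to and from
1-based closed coordinates happen only at the GFF3 boundary and in user
coordinate strings.
"""

from __future__ import annotations

import io
import json
import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import gffutils

logger = logging.getLogger("syntenica")

#: Number of columns in a PSL data line.
PSL_FIELDS = 21

#: Default assembly parameters: maximum gap (bp) bridged when chaining
#: liftover fragments, and the minimum assembled-fragment length expressed
#: as a percentage of the query length.
DEFAULT_GAP_VALUE = 200
DEFAULT_FILTERING_PCT = 16.0


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# PSL
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PslRecord:
    """One pairwise alignment line (PSL, 21 columns).

    Coordinates are 0-based half-open.  ``qStart``/``qEnd`` and
    ``tStart``/``tEnd`` are always forward-strand.  For ``strand == '-'``
    the per-block ``qStarts`` are, per PSL convention, coordinates on the
    reverse-complemented query; :meth:`query_blocks` converts back to
    forward-strand intervals.
    """

    matches: int
    misMatches: int
    repMatches: int
    nCount: int
    qNumInsert: int
    qBaseInsert: int
    tNumInsert: int
    tBaseInsert: int
    strand: str
    qName: str
    qSize: int
    qStart: int
    qEnd: int
    tName: str
    tSize: int
    tStart: int
    tEnd: int
    blockCount: int
    blockSizes: tuple[int, ...]
    qStarts: tuple[int, ...]
    tStarts: tuple[int, ...]

    def validate(self, where: str = "record") -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"{where}: unsupported strand {self.strand!r} "
                "(translated two-character strands are not accepted)"
            )
        if not (0 <= self.qStart < self.qEnd <= self.qSize):
            raise FormatError(f"{where}: query interval violates 0<=start<end<=size")
        if not (0 <= self.tStart < self.tEnd <= self.tSize):
            raise FormatError(f"{where}: target interval violates 0<=start<end<=size")
        n = self.blockCount
        if not (len(self.blockSizes) == len(self.qStarts) == len(self.tStarts) == n):
            raise FormatError(f"{where}: blockCount={n} does not match block list lengths")
        if n == 0:
            raise FormatError(f"{where}: blockCount must be >= 1")
        if any(s <= 0 for s in self.blockSizes):
            raise FormatError(f"{where}: non-positive block size")
        for i in range(1, n):
            if self.tStarts[i] < self.tStarts[i - 1] + self.blockSizes[i - 1]:
                raise FormatError(f"{where}: target blocks overlap or are out of order")
            if self.qStarts[i] < self.qStarts[i - 1] + self.blockSizes[i - 1]:
                raise FormatError(f"{where}: query blocks overlap or are out of order")
        if self.tStarts[0] < self.tStart or self.tStarts[-1] + self.blockSizes[-1] > self.tEnd:
            raise FormatError(f"{where}: target blocks outside tStart..tEnd")
        aligned = self.matches + self.misMatches + self.repMatches + self.nCount
        if sum(self.blockSizes) != aligned:
            raise FormatError(
                f"{where}: sum(blockSizes)={sum(self.blockSizes)} != "
                f"matches+misMatches+repMatches+nCount={aligned}"
            )

    # -- derived views ------------------------------------------------------

    @property
    def aligned_bases(self) -> int:
        return sum(self.blockSizes)

    def query_blocks(self) -> list[tuple[int, int]]:
        """Forward-strand query intervals of the blocks, ascending."""
        if self.strand == "+":
            return [(q, q + s) for q, s in zip(self.qStarts, self.blockSizes)]
        blocks = [(self.qSize - (q + s), self.qSize - q) for q, s in zip(self.qStarts, self.blockSizes)]
        return sorted(blocks)

    def target_blocks(self) -> list[tuple[int, int]]:
        return [(t, t + s) for t, s in zip(self.tStarts, self.blockSizes)]

    def block_pairs(self) -> list[tuple[int, int, int]]:
        """(q_forward_start, t_start, size) per block.

        For '-' strand the query start is the forward coordinate of the
        block's rightmost-mapping end, i.e. query coordinates decrease as
        target coordinates increase.
        """
        out = []
        for q, t, s in zip(self.qStarts, self.tStarts, self.blockSizes):
            if self.strand == "+":
                out.append((q, t, s))
            else:
                out.append((self.qSize - (q + s), t, s))
        return out

    def swapped(self) -> "PslRecord":
        """The same alignment with query and target roles exchanged."""
        if self.strand == "+":
            return replace(
                self,
                qNumInsert=self.tNumInsert,
                qBaseInsert=self.tBaseInsert,
                tNumInsert=self.qNumInsert,
                tBaseInsert=self.qBaseInsert,
                qName=self.tName,
                qSize=self.tSize,
                qStart=self.tStart,
                qEnd=self.tEnd,
                tName=self.qName,
                tSize=self.qSize,
                tStart=self.qStart,
                tEnd=self.qEnd,
                qStarts=self.tStarts,
                tStarts=self.qStarts,
            )
        # '-' strand: new query = old target, which must be expressed in
        # reverse coordinates; new target blocks must ascend, so block order
        # flips.
        sizes = tuple(reversed(self.blockSizes))
        new_q = tuple(self.tSize - (t + s) for t, s in zip(reversed(self.tStarts), sizes))
        new_t = tuple(self.qSize - (q + s) for q, s in zip(reversed(self.qStarts), sizes))
        rec = replace(
            self,
            qNumInsert=self.tNumInsert,
            qBaseInsert=self.tBaseInsert,
            tNumInsert=self.qNumInsert,
            tBaseInsert=self.qBaseInsert,
            qName=self.tName,
            qSize=self.tSize,
            qStart=self.tStart,
            qEnd=self.tEnd,
            tName=self.qName,
            tSize=self.qSize,
            tStart=self.qStart,
            tEnd=self.qEnd,
            blockSizes=sizes,
            qStarts=new_q,
            tStarts=new_t,
        )
        rec.validate("swapped record")
        return rec


def _int(value: str, lineno: int, col: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(f"line {lineno}: non-integer value {value!r} in column {col}") from None


def _int_list(value: str, lineno: int, col: str) -> tuple[int, ...]:
    items = [v for v in value.strip().split(",") if v != ""]
    return tuple(_int(v, lineno, col) for v in items)


def parse_psl(stream: io.TextIOBase | str | Iterable[str]) -> list[PslRecord]:
    """Parse a PSL stream (optionally headed by a 5-line psLayout block)."""
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]
    records: list[PslRecord] = []
    in_header = bool(lines) and lines[0].startswith("psLayout")
    for lineno, line in enumerate(lines, start=1):
        if in_header:
            if line.startswith("-"):
                in_header = False
            continue
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != PSL_FIELDS:
            raise FormatError(
                f"line {lineno}: expected {PSL_FIELDS} tab-separated fields, got {len(fields)}"
            )
        rec = PslRecord(
            matches=_int(fields[0], lineno, "matches"),
            misMatches=_int(fields[1], lineno, "misMatches"),
            repMatches=_int(fields[2], lineno, "repMatches"),
            nCount=_int(fields[3], lineno, "nCount"),
            qNumInsert=_int(fields[4], lineno, "qNumInsert"),
            qBaseInsert=_int(fields[5], lineno, "qBaseInsert"),
            tNumInsert=_int(fields[6], lineno, "tNumInsert"),
            tBaseInsert=_int(fields[7], lineno, "tBaseInsert"),
            strand=fields[8],
            qName=fields[9],
            qSize=_int(fields[10], lineno, "qSize"),
            qStart=_int(fields[11], lineno, "qStart"),
            qEnd=_int(fields[12], lineno, "qEnd"),
            tName=fields[13],
            tSize=_int(fields[14], lineno, "tSize"),
            tStart=_int(fields[15], lineno, "tStart"),
            tEnd=_int(fields[16], lineno, "tEnd"),
            blockCount=_int(fields[17], lineno, "blockCount"),
            blockSizes=_int_list(fields[18], lineno, "blockSizes"),
            qStarts=_int_list(fields[19], lineno, "qStarts"),
            tStarts=_int_list(fields[20], lineno, "tStarts"),
        )
        rec.validate(f"line {lineno}")
        records.append(rec)
    return records


def write_psl(records: Iterable[PslRecord]) -> str:
    """Serialize records as PSL text; inverse of :func:`parse_psl`."""
    out = []
    for r in records:
        out.append(
            "\t".join(
                str(v)
                for v in (
                    r.matches, r.misMatches, r.repMatches, r.nCount,
                    r.qNumInsert, r.qBaseInsert, r.tNumInsert, r.tBaseInsert,
                    r.strand, r.qName, r.qSize, r.qStart, r.qEnd,
                    r.tName, r.tSize, r.tStart, r.tEnd, r.blockCount,
                    ",".join(map(str, r.blockSizes)) + ",",
                    ",".join(map(str, r.qStarts)) + ",",
                    ",".join(map(str, r.tStarts)) + ",",
                )
            )
        )
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A gene with its exon/CDS/UTR intervals, 0-based half-open."""

    gene_id: str
    species: str
    seq_id: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    orthogroup_id: str | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    def introns(self) -> list[tuple[int, int]]:
        """Inter-exon gaps inside the gene span."""
        exons = sorted(self.exons)
        return [
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i + 1][0] > exons[i][1]
        ]

    def validate(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(f"gene {self.gene_id}: empty or negative span")
        for kind, ivs in (("exon", self.exons), ("CDS", self.cds),
                          ("five_prime_UTR", self.utr5), ("three_prime_UTR", self.utr3)):
            for s, e in ivs:
                if not (self.start <= s < e <= self.end):
                    raise FormatError(
                        f"gene {self.gene_id}: {kind} interval [{s},{e}) outside gene span"
                    )
        exons = sorted(self.exons)
        for i in range(1, len(exons)):
            if exons[i][0] < exons[i - 1][1]:
                raise FormatError(f"gene {self.gene_id}: overlapping exons")


_GFF_TYPES = {
    "exon": "exons",
    "CDS": "cds",
    "five_prime_UTR": "utr5",
    "three_prime_UTR": "utr3",
}


def parse_gff3(stream: io.TextIOBase | str, species: str) -> list[GeneModel]:
    """Parse generic GFF3 into gene models (one per ``gene`` feature).

    Sub-features are linked through ID/Parent across the gene -> mRNA ->
    exon/CDS/UTR hierarchy; coordinates come back 0-based half-open.
    Features whose Parent cannot be resolved are skipped with a warning.
    """
    text = stream if isinstance(stream, str) else stream.read()
    if not text.strip():
        return []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#") or not line.strip():
            continue
        if len(line.split("\t")) != 9:
            raise FormatError(f"line {lineno}: GFF3 lines need 9 tab-separated columns")
    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True,
        merge_strategy="create_unique", keep_order=True, force=True,
    )
    known_ids = {f.id for f in db.all_features()}
    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene", order_by=("seqid", "start")):
        model = GeneModel(
            gene_id=gf.id,
            species=species,
            seq_id=gf.seqid,
            start=gf.start - 1,
            end=gf.end,
            strand=gf.strand,
            orthogroup_id=gf.attributes.get("orthogroup", [None])[0],
        )
        for child in db.children(gf.id):
            attr = _GFF_TYPES.get(child.featuretype)
            if attr is not None:
                getattr(model, attr).append((child.start - 1, child.end))
        for attr in _GFF_TYPES.values():
            ivs = sorted(set(getattr(model, attr)))
            setattr(model, attr, ivs)
        model.validate()
        genes.append(model)
    for f in db.all_features():
        for parent in f.attributes.get("Parent", []):
            if parent not in known_ids:
                logger.warning("GFF3 feature %s has unknown Parent %s; skipped", f.id, parent)
    return genes


def write_gff3(genes: Iterable[GeneModel]) -> str:
    """Serialize gene models as GFF3 (gene/mRNA/exon/CDS/UTR hierarchy)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.seq_id, g.start)):
        attrs = f"ID={g.gene_id}"
        if g.orthogroup_id:
            attrs += f";orthogroup={g.orthogroup_id}"
        lines.append(
            f"{g.seq_id}\tsyntenica\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        mrna = f"{g.gene_id}.t1"
        lines.append(
            f"{g.seq_id}\tsyntenica\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={mrna};Parent={g.gene_id}"
        )
        for ftype, ivs in (
            ("exon", g.exons), ("CDS", g.cds),
            ("five_prime_UTR", g.utr5), ("three_prime_UTR", g.utr3),
        ):
            for i, (s, e) in enumerate(sorted(ivs), start=1):
                lines.append(
                    f"{g.seq_id}\tsyntenica\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.{ftype}.{i};Parent={mrna}"
                )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Orthogroup table
# ---------------------------------------------------------------------------


@dataclass
class OrthogroupTable:
    """orthogroup id -> {species -> gene ids}; each gene in at most one OG."""

    groups: dict[str, dict[str, list[str]]]

    def __post_init__(self) -> None:
        self._gene_index: dict[str, str] = {}
        for og, per_sp in self.groups.items():
            for genes in per_sp.values():
                for g in genes:
                    if g in self._gene_index:
                        raise FormatError(
                            f"gene {g} assigned to both {self._gene_index[g]} and {og}"
                        )
                    self._gene_index[g] = og

    def og_of(self, gene_id: str) -> str | None:
        return self._gene_index.get(gene_id)

    def members(self, og_id: str) -> dict[str, list[str]]:
        return self.groups[og_id]

    def species_with_member(self, og_id: str) -> list[str]:
        return [sp for sp, genes in self.groups[og_id].items() if genes]

    def __len__(self) -> int:
        return len(self.groups)

    def __contains__(self, og_id: str) -> bool:
        return og_id in self.groups


def parse_orthogroups(stream: io.TextIOBase | str) -> OrthogroupTable:
    """Parse a TSV orthogroup table.

    Column 1 is the orthogroup id; the header row names the species of the
    remaining columns, whose cells hold comma-separated gene ids.
    """
    text = stream if isinstance(stream, str) else stream.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return OrthogroupTable({})
    header = lines[0].split("\t")
    species = header[1:]
    if not species:
        raise FormatError("orthogroup table needs at least one species column")
    groups: dict[str, dict[str, list[str]]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(f"line {lineno}: expected {len(header)} columns")
        og = cells[0]
        if og in groups:
            raise FormatError(f"line {lineno}: duplicate orthogroup id {og}")
        groups[og] = {
            sp: [g for g in cell.replace(", ", ",").split(",") if g]
            for sp, cell in zip(species, cells[1:])
        }
    return OrthogroupTable(groups)


def write_orthogroups(table: OrthogroupTable, species_order: Sequence[str]) -> str:
    lines = ["\t".join(["Orthogroup", *species_order])]
    for og in sorted(table.groups):
        per_sp = table.groups[og]
        lines.append("\t".join([og, *(",".join(per_sp.get(sp, [])) for sp in species_order)]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Species guide tree
# ---------------------------------------------------------------------------


@dataclass
class SpeciesTree:
    """A rooted guide tree; leaf order fixes the plot's track order."""

    tree: dendropy.Tree

    @property
    def display_order(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def adjacent_pairs(self) -> list[tuple[str, str]]:
        order = self.display_order
        return list(zip(order, order[1:]))

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def parse_tree(stream: io.TextIOBase | str) -> SpeciesTree:
    text = stream if isinstance(stream, str) else stream.read()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"unparseable newick tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError("newick leaf labels are not unique")
    return SpeciesTree(tree)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamSet:
    """The two user-facing assembly parameters.

    ``gap_value`` (bp) is the maximum gap allowed between adjacent liftover
    fragments for them to be assembled into one larger fragment;
    ``filtering_pct`` is the minimum assembled-fragment length as a
    percentage of the query length for the fragment to be kept.
    """

    gap_value: int = DEFAULT_GAP_VALUE
    filtering_pct: float = DEFAULT_FILTERING_PCT

    def __post_init__(self) -> None:
        if self.gap_value < 0:
            raise ValueError("gap_value must be >= 0")
        if not (0 <= self.filtering_pct <= 100):
            raise ValueError("filtering_pct must be in [0, 100]")


# ---------------------------------------------------------------------------
# On-disk dataset bundle
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """A directory bundle of everything one clade analysis needs.

    Layout::

        tree.nwk                    species guide tree
        genomes.tsv                 species, seq_id, length
        reference.txt               name of the reference species
        orthogroups.tsv             orthogroup table
        annotations/<species>.gff3  per-species gene models
        psl/<ref>_vs_<species>.psl  liftover alignments, query = reference
        psl_pairs/<a>__<b>.psl      alignments between display-adjacent pairs
        dup_events.tsv              mutation-event table (species, class, size)
        truth.json                  simulator ground truth (synthetic data only)
    """

    root: Path
    tree: SpeciesTree
    reference: str
    genomes: dict[str, dict[str, int]]
    annotations: dict[str, list[GeneModel]]
    orthogroups: OrthogroupTable
    alignments: dict[str, list[PslRecord]]
    pairwise: dict[tuple[str, str], list[PslRecord]]
    truth: dict | None = None

    @property
    def species(self) -> list[str]:
        return self.tree.display_order

    def genes_by_id(self, species: str) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.annotations.get(species, [])}

    @classmethod
    def load(cls, root: str | os.PathLike) -> "Dataset":
        root = Path(root)
        tree = parse_tree((root / "tree.nwk").read_text())
        reference = (root / "reference.txt").read_text().strip()
        genomes: dict[str, dict[str, int]] = {}
        for line in (root / "genomes.tsv").read_text().splitlines()[1:]:
            if not line.strip():
                continue
            sp, seq, length = line.split("\t")
            genomes.setdefault(sp, {})[seq] = int(length)
        annotations = {}
        for sp in tree.display_order:
            gff = root / "annotations" / f"{sp}.gff3"
            annotations[sp] = parse_gff3(gff.read_text(), sp) if gff.exists() else []
        orthogroups = parse_orthogroups((root / "orthogroups.tsv").read_text())
        for sp, models in annotations.items():
            for g in models:
                g.orthogroup_id = orthogroups.og_of(g.gene_id)
        alignments = {}
        for sp in tree.display_order:
            if sp == reference:
                continue
            psl = root / "psl" / f"{reference}_vs_{sp}.psl"
            if psl.exists():
                alignments[sp] = parse_psl(psl.read_text())
            else:
                logger.warning("missing liftover PSL for %s", sp)
                alignments[sp] = []
        pairwise = {}
        for a, b in tree.adjacent_pairs():
            psl = root / "psl_pairs" / f"{a}__{b}.psl"
            if psl.exists():
                pairwise[(a, b)] = parse_psl(psl.read_text())
        truth_path = root / "truth.json"
        truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
        return cls(
            root=root, tree=tree, reference=reference, genomes=genomes,
            annotations=annotations, orthogroups=orthogroups,
            alignments=alignments, pairwise=pairwise, truth=truth,
        )
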