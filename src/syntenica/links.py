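"""Pairwise synteny links between species adjacent in the display order.

Given the fragments displayed for each species and the pairwise alignment
PSL between two display-adjacent species, links are the gap-merged chains
of alignment blocks that fall inside both species' displayed fragments.
They are drawn as ribbons between neighbouring tracks; an inverted link
(the two sides on opposite orientations) renders as a crossing ribbon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .assembly import FragmentSet
from .formats import PslRecord

logger = logging.getLogger("syntenica")


@dataclass(frozen=True)
class SyntenyLink:
    species_a: str
    species_b: str
    seq_a: str
    start_a: int
    end_a: int
    seq_b: str
    start_b: int
    end_b: int
    strand_relation: str  # 'same' | 'inverted'
    support: int  # aligned bases

    def __post_init__(self) -> None:
        if self.support <= 0:
            raise ValueError("link support must be > 0")


def _windows(fset: FragmentSet | None) -> dict[str, list[tuple[int, int]]]:
    spans: dict[str, list[tuple[int, int]]] = {}
    if fset is None:
        return spans
    for f in fset.displayed():
        spans.setdefault(f.t_seq, []).append((f.t_start, f.t_end))
    for seq in spans:
        spans[seq] = sorted(spans[seq])
    return spans


def _intersect(iv: tuple[int, int], windows: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for w0, w1 in windows:
        x0, x1 = max(iv[0], w0), min(iv[1], w1)
        if x1 > x0:
            out.append((x0, x1))
    return out


def _clip_block(
    qf0: int, t0: int, size: int, orient: str,
    q_windows: Mapping[str, list[tuple[int, int]]] | None,
    t_windows: Mapping[str, list[tuple[int, int]]] | None,
    q_seq: str, t_seq: str,
) -> list[tuple[int, int, int]]:
    """Clip one aligned block to window sets on both sides.

    Returns (q_forward_start, t_start, size) pieces.  For an inverted
    block, query-forward coordinates run opposite to target coordinates.
    """
    t_pieces = (
        _intersect((t0, t0 + size), t_windows.get(t_seq, []))
        if t_windows is not None
        else [(t0, t0 + size)]
    )
    out = []
    for x0, x1 in t_pieces:
        if orient == "+":
            q0, q1 = qf0 + (x0 - t0), qf0 + (x1 - t0)
        else:
            q0, q1 = qf0 + (t0 + size - x1), qf0 + (t0 + size - x0)
        q_pieces = (
            _intersect((q0, q1), q_windows.get(q_seq, []))
            if q_windows is not None
            else [(q0, q1)]
        )
        for y0, y1 in q_pieces:
            if orient == "+":
                tt0 = x0 + (y0 - q0)
            else:
                tt0 = x0 + (q1 - y1)
            out.append((y0, tt0, y1 - y0))
    return out


def _interval_gap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, max(a0, b0) - min(a1, b1))


def build_links(
    fragment_sets: Mapping[str, FragmentSet],
    display_order: Sequence[str],
    pairwise: Mapping[tuple[str, str], Sequence[PslRecord]],
    gap_value: int,
    clip: bool = True,
) -> list[SyntenyLink]:
    """Build links for every adjacent species pair in display order.

    Alignment blocks are clipped to both species' displayed fragments
    (unless ``clip`` is False), then chained under the assembly gap rule
    applied on both sides.  Pairs with no pairwise PSL produce a warning
    and no links.
    """
    links: list[SyntenyLink] = []
    for a, b in zip(display_order, display_order[1:]):
        records = pairwise.get((a, b))
        swapped = False
        if records is None:
            rev = pairwise.get((b, a))
            if rev is not None:
                records = [r.swapped() for r in rev]
                swapped = True
        if records is None:
            logger.warning("no pairwise alignment for (%s, %s); links skipped", a, b)
            continue
        a_windows = _windows(fragment_sets.get(a)) if clip else None
        b_windows = _windows(fragment_sets.get(b)) if clip else None
        # collect clipped blocks grouped by (seq_a, seq_b, orientation)
        groups: dict[tuple[str, str, str], list[tuple[int, int, int]]] = {}
        for r in records:
            for qf0, t0, size in r.block_pairs():
                pieces = _clip_block(
                    qf0, t0, size, r.strand, a_windows, b_windows, r.qName, r.tName
                )
                for piece in pieces:
                    groups.setdefault((r.qName, r.tName, r.strand), []).append(piece)
        for (seq_a, seq_b, orient), blocks in sorted(groups.items()):
            blocks.sort(key=lambda blk: (blk[1], blk[0]))
            chain: list[tuple[int, int, int]] = []

            def flush(chain: list[tuple[int, int, int]]) -> None:
                if not chain:
                    return
                q0 = min(q for q, _, _ in chain)
                q1 = max(q + s for q, _, s in chain)
                t0 = min(t for _, t, _ in chain)
                t1 = max(t + s for _, t, s in chain)
                links.append(
                    SyntenyLink(
                        species_a=a, species_b=b, seq_a=seq_a,
                        start_a=q0, end_a=q1, seq_b=seq_b, start_b=t0, end_b=t1,
                        strand_relation="same" if orient == "+" else "inverted",
                        support=sum(s for _, _, s in chain),
                    )
                )

            cur_q: tuple[int, int] | None = None
            cur_t: tuple[int, int] | None = None
            for q, t, s in blocks:
                if cur_q is None:
                    chain = [(q, t, s)]
                    cur_q, cur_t = (q, q + s), (t, t + s)
                    continue
                gq = _interval_gap(cur_q[0], cur_q[1], q, q + s)
                gt = _interval_gap(cur_t[0], cur_t[1], t, t + s)
                if gq <= gap_value and gt <= gap_value:
                    chain.append((q, t, s))
                    cur_q = (min(cur_q[0], q), max(cur_q[1], q + s))
                    cur_t = (min(cur_t[0], t), max(cur_t[1], t + s))
                else:
                    flush(chain)
                    chain = [(q, t, s)]
                    cur_q, cur_t = (q, q + s), (t, t + s)
            flush(chain)
        if swapped:
            pass  # links already expressed with a as species_a
    return links


def links_table(links: Sequence[SyntenyLink]) -> str:
    lines = [
        "species_a\tseq_a\tstart_a\tend_a\tspecies_b\tseq_b\tstart_b\tend_b"
        "\torientation\tsupport"
    ]
    for ln in links:
        lines.append(
            f"{ln.species_a}\t{ln.seq_a}\t{ln.start_a}\t{ln.end_a}"
            f"\t{ln.species_b}\t{ln.seq_b}\t{ln.start_b}\t{ln.end_b}"
            f"\t{ln.strand_relation}\t{ln.support}"
        )
    return "\n".join(lines) + "\n"
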