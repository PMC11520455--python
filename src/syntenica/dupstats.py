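"""Duplication-event size summaries and sister-pair comparisons.

Consumes a mutation-event table (TSV: species, class, size) such as the
per-branch event summaries exported from a multi-genome alignment, bins
duplication events by size (events under 50 bp are excluded by default),
and compares sister species — e.g. a self-fertilizing species against its
outcrossing sister — with a paired t-test over the size bins.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_SIZE = 50
#: Size-class lower edges (bp); the last class is open-ended.
DEFAULT_BINS = (50, 100, 250, 500, 1000, 5000)


@dataclass(frozen=True)
class DupEvent:
    species: str
    size: int
    event_class: str = "duplication"

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("event size must be > 0")


def parse_events(stream: io.TextIOBase | str) -> list[DupEvent]:
    """Parse a TSV event table with columns species, class, size."""
    text = stream if isinstance(stream, str) else stream.read()
    df = pd.read_csv(io.StringIO(text), sep="\t")
    required = {"species", "class", "size"}
    if not required.issubset(df.columns):
        raise ValueError(f"event table needs columns {sorted(required)}")
    return [
        DupEvent(species=str(row["species"]), size=int(row["size"]), event_class=str(row["class"]))
        for _, row in df.iterrows()
    ]


def duplication_size_table(
    events: Iterable[DupEvent],
    min_size: int = DEFAULT_MIN_SIZE,
    bins: Sequence[int] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Counts of duplication events per species and size class.

    Non-duplication event classes are ignored; events smaller than
    ``min_size`` are excluded.  ``bins`` are the lower edges of the size
    classes; the last class is open-ended.  The number of excluded events
    is stored in ``df.attrs['excluded']``.
    """
    bins = list(bins)
    if not bins or any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
        raise ValueError("bins must be a non-empty strictly increasing sequence")
    dups = [e for e in events if e.event_class == "duplication"]
    kept = [e for e in dups if e.size >= min_size]
    edges = bins + [math.inf]
    labels = [
        f"{lo}-{int(hi) - 1}" if math.isfinite(hi) else f">={lo}"
        for lo, hi in zip(edges, edges[1:])
    ]
    species = sorted({e.species for e in dups})
    table = pd.DataFrame(0, index=species, columns=labels, dtype=int)
    for e in kept:
        if e.size < edges[0]:
            continue
        for lo, hi, lab in zip(edges, edges[1:], labels):
            if lo <= e.size < hi:
                table.loc[e.species, lab] += 1
                break
    table.attrs["excluded"] = len(dups) - sum(int(x) for x in table.to_numpy().ravel())
    table.attrs["min_size"] = min_size
    return table


@dataclass(frozen=True)
class PairComparison:
    species_a: str
    species_b: str
    t_statistic: float
    p_value: float
    total_a: int
    total_b: int
    n_bins: int
    degenerate: bool = False
    note: str = ""


def sister_pair_comparison(
    counts: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
) -> list[PairComparison]:
    """Paired t-test over size-bin counts for each sister-species pair.

    Degenerate zero-variance differences are reported as t = 0, p = 1 when
    the counts are identical and t = ±inf, p = 0 (flagged) when the
    difference is a non-zero constant.  Missing species give an NA row.
    """
    out: list[PairComparison] = []
    for a, b in pairs:
        if a not in counts.index or b not in counts.index or len(counts.columns) < 2:
            missing = [s for s in (a, b) if s not in counts.index]
            note = f"missing species: {', '.join(missing)}" if missing else "fewer than 2 bins"
            out.append(
                PairComparison(a, b, math.nan, math.nan, 0, 0, len(counts.columns), note=note)
            )
            continue
        va = counts.loc[a].to_numpy(dtype=float)
        vb = counts.loc[b].to_numpy(dtype=float)
        diffs = va - vb
        if np.allclose(diffs.std(ddof=1), 0.0):
            if np.allclose(diffs, 0.0):
                t, p, degenerate = 0.0, 1.0, False
            else:
                t = math.inf if diffs[0] > 0 else -math.inf
                p, degenerate = 0.0, True
        else:
            t, p = stats.ttest_rel(va, vb)
            t, p, degenerate = float(t), float(p), False
        out.append(
            PairComparison(
                a, b, t, p, int(va.sum()), int(vb.sum()), len(counts.columns),
                degenerate=degenerate,
            )
        )
    return out


def comparison_table(comparisons: Sequence[PairComparison]) -> str:
    lines = ["species_a\tspecies_b\tt\tp\ttotal_a\ttotal_b\tn_bins\tdegenerate\tnote"]
    for c in comparisons:
        lines.append(
            f"{c.species_a}\t{c.species_b}\t{c.t_statistic:.6g}\t{c.p_value:.6g}"
            f"\t{c.total_a}\t{c.total_b}\t{c.n_bins}\t{c.degenerate}\t{c.note}"
        )
    return "\n".join(lines) + "\n"
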