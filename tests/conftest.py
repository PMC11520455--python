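"""Shared fixtures: the golden synthetic clade and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from syntenica.formats import PslRecord
from syntenica.simulate import SimConfig, simulate_clade, simulate_dataset


@pytest.fixture(scope="session")
def golden_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("golden")


@pytest.fixture(scope="session")
def golden_dataset(golden_dir):
    """The golden fixture: 5 species, 100 genes, seed 42, written to disk."""
    return simulate_dataset(SimConfig(), golden_dir / "clade")


@pytest.fixture(scope="session")
def null_clade():
    """Null evolution: every species an exact copy of the ancestor."""
    return simulate_clade(SimConfig.null(n_genes=20))


def make_record(
    t_start: int,
    t_end: int,
    q_start: int = 0,
    t_name: str = "chrT",
    q_name: str = "chrQ",
    strand: str = "+",
    q_size: int = 100_000,
    t_size: int = 100_000,
    matches: int | None = None,
) -> PslRecord:
    """A single-block PSL record for assembly tests."""
    size = t_end - t_start
    m = size if matches is None else matches
    return PslRecord(
        matches=m, misMatches=size - m, repMatches=0, nCount=0,
        qNumInsert=0, qBaseInsert=0, tNumInsert=0, tBaseInsert=0,
        strand=strand, qName=q_name, qSize=q_size,
        qStart=q_start, qEnd=q_start + size,
        tName=t_name, tSize=t_size, tStart=t_start, tEnd=t_end,
        blockCount=1, blockSizes=(size,),
        qStarts=(q_start if strand == "+" else q_size - (q_start + size),),
        tStarts=(t_start,),
    )


def brute_force_assembly(records, gap_value):
    """Merge-closure oracle: repeatedly merge any two chainable groups.

    Two groups merge iff they share (tName, strand) and the gap between
    their target spans is <= gap_value.  Returns a sorted list of
    (tName, strand, t_start, t_end, frozenset(member indices)).
    """
    groups = [
        {"key": (r.tName, r.strand), "lo": r.tStart, "hi": r.tEnd, "members": {i}}
        for i, r in enumerate(records)
    ]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = groups[i], groups[j]
                if a["key"] != b["key"]:
                    continue
                gap = max(a["lo"], b["lo"]) - min(a["hi"], b["hi"])
                if gap <= gap_value:
                    a["lo"] = min(a["lo"], b["lo"])
                    a["hi"] = max(a["hi"], b["hi"])
                    a["members"] |= b["members"]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(
        (g["key"][0], g["key"][1], g["lo"], g["hi"], frozenset(g["members"]))
        for g in groups
    )


def random_instance(rng: np.random.Generator, max_records: int = 8):
    """A random assembly instance: records on 1-2 target sequences."""
    n = int(rng.integers(1, max_records + 1))
    records = []
    for _ in range(n):
        t_name = "chrT" + str(rng.integers(1, 3))
        strand = "+" if rng.random() < 0.8 else "-"
        t0 = int(rng.integers(0, 5000))
        size = int(rng.integers(1, 400))
        q0 = int(rng.integers(0, 5000))
        records.append(
            make_record(t0, t0 + size, q_start=q0, t_name=t_name, strand=strand)
        )
    gap = int(rng.integers(0, 500))
    return records, gap
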