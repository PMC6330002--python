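from __future__ import annotations

import numpy as np
import pytest

from qualcrunch.pileup import ReadRecord


def parse_cigar(text: str):
    out = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


def mk_read(
    pos: int,
    cigar: str,
    seq: str | None = None,
    qual=None,
    name: str = "r",
    mapq: int = 60,
    flags: int = 0,
    ref_id: int = 0,
) -> ReadRecord:
    ops = parse_cigar(cigar)
    qlen = sum(ln for op, ln in ops if op in "MIS=X")
    if seq is None:
        seq = "A" * qlen
    if qual is None:
        qual = [30] * qlen
    return ReadRecord(
        name=name, ref_id=ref_id, pos=pos, cigar=ops, seq=seq,
        qual=np.asarray(qual, dtype=np.int16), mapq=mapq, flags=flags,
    )


def random_column_entries(rng: np.random.Generator, max_depth: int = 20):
    """Random (base, qual, mapq) triples for oracle cross-checks.

    MAPQ stays >= 1 so mismatch penalties are never zero (the pessimism
    equality-iff-clean invariant needs non-degenerate weights).
    """
    depth = int(rng.integers(0, max_depth + 1))
    bases = rng.choice(list("ACGT*N"), size=depth, p=[0.3, 0.25, 0.2, 0.15, 0.06, 0.04])
    quals = rng.integers(2, 42, size=depth)
    mapqs = rng.integers(1, 61, size=depth)
    return [(str(b), int(q), int(m)) for b, q, m in zip(bases, quals, mapqs)]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def column_from_entries(pos: int, entries):
    """Build a PileupColumn directly from (base, qual, mapq) triples."""
    from qualcrunch.pileup import PileupColumn, PileupEntry

    dummy = mk_read(pos, "1M", "A", [30], name="dummy")
    return PileupColumn(
        ref_id=0,
        pos=pos,
        entries=[
            PileupEntry(base=b, qual=q, mapq=m, read=dummy, qpos=None if b == "*" else 0,
                        strand="+")
            for b, q, m in entries
        ],
    )
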