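"""Pileup construction over coordinate-sorted aligned reads.

Overlapping reads are expanded into per-locus columns.  A deletion is
treated as a fifth base type (``'*'``) and contributes exactly one entry at
every deleted locus; soft-clipped bases never enter a column; insertions do
not create columns but are recorded per read so the rewrite stage can
handle their qualities.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

# Base codes used everywhere downstream.
A, C, G, T, STAR, N = range(6)
ALPHABET = "ACGT*N"

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

# SAM flag bits.
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUP = 0x400
FLAG_SUPPLEMENTARY = 0x800

#: Records carrying any of these flags pass through untouched and are
#: excluded from pileup columns.
EXCLUDE_FLAGS = (
    FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_QCFAIL | FLAG_DUP | FLAG_SUPPLEMENTARY
)

CONSUMES_QUERY = frozenset("MIS=X")
CONSUMES_REF = frozenset("MDN=X")
_VALID_OPS = frozenset("MIDNSHP=X")

MAPQ_UNAVAILABLE = 255
#: MAPQ 255 means "unavailable"; it is substituted with this neutral value.
DEFAULT_MAPQ_SUBSTITUTE = 30


def encode_bases(seq: str) -> np.ndarray:
    """Map a base string onto uint8 codes (unknown letters become N)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(eq=False)
class ReadRecord:
    """One aligned read: alignment, bases, Phred qualities, MAPQ, flags.

    ``qual`` is stored as an int16 numpy array; ``cigar`` is a list of
    ``(op, length)`` with op one of ``MIDNSHP=X``.  Identity semantics
    (``eq=False``) are intentional: retention masks track reads by object.
    """

    name: str
    ref_id: int
    pos: int
    cigar: List[Tuple[str, int]]
    seq: str
    qual: np.ndarray
    mapq: int = 60
    flags: int = 0
    aux: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=np.int16)
        self._ref_end: Optional[int] = None

    # -- derived properties -------------------------------------------------
    @property
    def is_reverse(self) -> bool:
        return bool(self.flags & FLAG_REVERSE)

    @property
    def eligible(self) -> bool:
        """True if the read participates in pileup columns."""
        return not (self.flags & EXCLUDE_FLAGS)

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    def query_consumed(self) -> int:
        return sum(ln for op, ln in self.cigar if op in CONSUMES_QUERY)

    def ref_consumed(self) -> int:
        return sum(ln for op, ln in self.cigar if op in CONSUMES_REF)

    @property
    def ref_end(self) -> int:
        """One past the last reference base consumed by the alignment.

        Cached on first access; the alignment fields are treated as frozen
        from that point on.
        """
        if self._ref_end is None:
            self._ref_end = self.pos + self.ref_consumed()
        return self._ref_end

    def validate(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.name!r}: seq length {len(self.seq)} != "
                f"qual length {len(self.qual)}"
            )
        for op, ln in self.cigar:
            if op not in _VALID_OPS or ln <= 0:
                raise ValueError(f"read {self.name!r}: bad CIGAR op {op}{ln}")
        qc = self.query_consumed()
        if qc != len(self.seq):
            raise ValueError(
                f"read {self.name!r}: CIGAR consumes {qc} query bases but "
                f"seq has {len(self.seq)}"
            )


@dataclass
class PileupEntry:
    base: str
    qual: int
    mapq: int
    read: ReadRecord
    qpos: Optional[int]  # None for '*'
    strand: str


@dataclass
class PileupColumn:
    ref_id: int
    pos: int
    entries: List[PileupEntry]

    @property
    def depth(self) -> int:
        return len(self.entries)


@dataclass
class Entries:
    """Struct-of-arrays expansion of a window of reads.

    ``mapq`` holds the effective per-entry mapping quality (255 already
    substituted).  ``qpos`` is -1 for deletion entries.
    """

    start: int
    end: int
    pos: np.ndarray
    base: np.ndarray
    qual: np.ndarray
    mapq: np.ndarray
    read_index: np.ndarray
    qpos: np.ndarray
    reads: Sequence[ReadRecord]
    insertions: List[Tuple[int, int, int, int]]  # (read_idx, ref_anchor, qpos, len)
    deletions: List[Tuple[int, int, int]]  # (read_idx, ref_start, ref_end)

    def __len__(self) -> int:
        return len(self.pos)

    def depth_profile(self) -> np.ndarray:
        """Per-locus entry count over [start, end)."""
        return np.bincount(
            (self.pos - self.start).astype(np.int64), minlength=self.end - self.start
        )

    def base_count_grid(self) -> np.ndarray:
        """(npos, 6) per-locus counts for each base code."""
        npos = self.end - self.start
        flat = (self.pos - self.start) * 6 + self.base
        return np.bincount(flat.astype(np.int64), minlength=npos * 6).reshape(npos, 6)

    def indel_spans(self) -> List[Tuple[int, int]]:
        """Reference spans touched by indels (insertions as 1-wide anchors)."""
        spans = [(s, e) for _, s, e in self.deletions]
        spans += [(anchor, anchor + 1) for _, anchor, _, _ in self.insertions]
        return spans


def _deletion_qual(qual: np.ndarray, q: int) -> int:
    """Flanking-average quality attributed to '*' entries (rounded down)."""
    n = len(qual)
    left = int(qual[q - 1]) if q > 0 else None
    right = int(qual[q]) if q < n else None
    if left is None and right is None:
        return 0
    if left is None:
        return right
    if right is None:
        return left
    return (left + right) // 2


def _expand_complex(
    read: ReadRecord,
    idx: int,
    start: int,
    end: int,
    eff_mapq: int,
    out: dict,
) -> None:
    bases = encode_bases(read.seq)
    rpos = read.pos
    q = 0
    for op, ln in read.cigar:
        if op in "M=X":
            lo = max(rpos, start)
            hi = min(rpos + ln, end)
            if lo < hi:
                off = lo - rpos
                k = hi - lo
                out["pos"].append(np.arange(lo, hi, dtype=np.int64))
                out["base"].append(bases[q + off : q + off + k])
                out["qual"].append(read.qual[q + off : q + off + k])
                out["mapq"].append(np.full(k, eff_mapq, dtype=np.int16))
                out["ridx"].append(np.full(k, idx, dtype=np.int32))
                out["qpos"].append(np.arange(q + off, q + off + k, dtype=np.int32))
            rpos += ln
            q += ln
        elif op == "I":
            out["insertions"].append((idx, rpos, q, ln))
            q += ln
        elif op == "S":
            q += ln
        elif op == "D":
            dq = _deletion_qual(read.qual, q)
            out["deletions"].append((idx, rpos, rpos + ln))
            lo = max(rpos, start)
            hi = min(rpos + ln, end)
            if lo < hi:
                k = hi - lo
                out["pos"].append(np.arange(lo, hi, dtype=np.int64))
                out["base"].append(np.full(k, STAR, dtype=np.uint8))
                out["qual"].append(np.full(k, dq, dtype=np.int16))
                out["mapq"].append(np.full(k, eff_mapq, dtype=np.int16))
                out["ridx"].append(np.full(k, idx, dtype=np.int32))
                out["qpos"].append(np.full(k, -1, dtype=np.int32))
            rpos += ln
        elif op == "N":
            rpos += ln
        # H and P consume nothing we track.


def expand_reads(
    reads: Sequence[ReadRecord],
    span: Tuple[int, int],
    mapq_substitute: int = DEFAULT_MAPQ_SUBSTITUTE,
) -> Entries:
    """Expand eligible reads into flat per-entry arrays clipped to ``span``.

    Ineligible reads (unmapped/secondary/supplementary/duplicate/QC-fail)
    contribute nothing.
    """
    start, end = span
    out = {
        "pos": [],
        "base": [],
        "qual": [],
        "mapq": [],
        "ridx": [],
        "qpos": [],
        "insertions": [],
        "deletions": [],
    }
    # All-M reads are the overwhelmingly common case; batch them per length.
    simple_by_len: dict = {}
    for i, r in enumerate(reads):
        if not r.eligible:
            continue
        if r.pos >= end or r.ref_end <= start:
            continue
        cig = r.cigar
        if len(cig) == 1 and cig[0][0] in "M=":
            simple_by_len.setdefault(cig[0][1], []).append(i)
        else:
            eff = mapq_substitute if r.mapq == MAPQ_UNAVAILABLE else r.mapq
            _expand_complex(r, i, start, end, eff, out)
    for L, idxs in simple_by_len.items():
        n = len(idxs)
        starts = np.array([reads[i].pos for i in idxs], dtype=np.int64)
        mapqs = np.array(
            [
                mapq_substitute
                if reads[i].mapq == MAPQ_UNAVAILABLE
                else reads[i].mapq
                for i in idxs
            ],
            dtype=np.int16,
        )
        offs = np.arange(L, dtype=np.int64)
        pos = (starts[:, None] + offs[None, :]).ravel()
        base = np.concatenate([encode_bases(reads[i].seq) for i in idxs])
        qual = np.concatenate([reads[i].qual for i in idxs])
        mapq = np.repeat(mapqs, L)
        ridx = np.repeat(np.asarray(idxs, dtype=np.int32), L)
        qpos = np.tile(offs.astype(np.int32), n)
        keep = (pos >= start) & (pos < end)
        out["pos"].append(pos[keep])
        out["base"].append(base[keep])
        out["qual"].append(qual[keep])
        out["mapq"].append(mapq[keep])
        out["ridx"].append(ridx[keep])
        out["qpos"].append(qpos[keep])

    if out["pos"]:
        pos = np.concatenate(out["pos"])
        base = np.concatenate(out["base"])
        qual = np.concatenate(out["qual"])
        mapq = np.concatenate(out["mapq"])
        ridx = np.concatenate(out["ridx"])
        qpos = np.concatenate(out["qpos"])
        order = np.lexsort((qpos, ridx, pos))
        pos, base, qual, mapq, ridx, qpos = (
            a[order] for a in (pos, base, qual, mapq, ridx, qpos)
        )
    else:
        pos = np.empty(0, dtype=np.int64)
        base = np.empty(0, dtype=np.uint8)
        qual = np.empty(0, dtype=np.int16)
        mapq = np.empty(0, dtype=np.int16)
        ridx = np.empty(0, dtype=np.int32)
        qpos = np.empty(0, dtype=np.int32)
    return Entries(
        start=start,
        end=end,
        pos=pos,
        base=base,
        qual=qual,
        mapq=mapq,
        read_index=ridx,
        qpos=qpos,
        reads=reads,
        insertions=out["insertions"],
        deletions=out["deletions"],
    )


def check_sorted(reads: Iterable[ReadRecord]) -> None:
    last = None
    for r in reads:
        key = (r.ref_id, r.pos)
        if last is not None and key < last:
            raise ValueError(
                f"input not coordinate-sorted at read {r.name!r} "
                f"(ref {r.ref_id}, pos {r.pos})"
            )
        last = key


def build_pileup(
    reads: Sequence[ReadRecord],
    span: Tuple[int, int],
    mapq_substitute: int = DEFAULT_MAPQ_SUBSTITUTE,
) -> List[PileupColumn]:
    """One :class:`PileupColumn` per covered locus in ``span``, ordered by pos.

    Raises ``ValueError`` on unsorted input (naming the offending read) or
    on a CIGAR/sequence length mismatch.
    """
    check_sorted(reads)
    for r in reads:
        if r.eligible:
            r.validate()
    ref_ids = {r.ref_id for r in reads if r.eligible}
    if len(ref_ids) > 1:
        raise ValueError("build_pileup expects reads from a single reference")
    ref_id = ref_ids.pop() if ref_ids else -1
    ent = expand_reads(reads, span, mapq_substitute=mapq_substitute)
    cols: List[PileupColumn] = []
    if len(ent) == 0:
        return cols
    boundaries = np.flatnonzero(np.diff(ent.pos)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(ent)]))
    for s, e in zip(starts, ends):
        p = int(ent.pos[s])
        entries = []
        for k in range(s, e):
            read = ent.reads[int(ent.read_index[k])]
            code = int(ent.base[k])
            entries.append(
                PileupEntry(
                    base=ALPHABET[code],
                    qual=int(ent.qual[k]),
                    mapq=int(ent.mapq[k]),
                    read=read,
                    qpos=None if code == STAR else int(ent.qpos[k]),
                    strand=read.strand,
                )
            )
        cols.append(PileupColumn(ref_id=ref_id, pos=p, entries=entries))
    return cols


def softclip_positions(read: ReadRecord) -> List[Tuple[int, str, int]]:
    """Soft-clip anchor sites for one read.

    A left clip maps to ``read.pos``; a right clip maps to one past the
    last aligned reference base.  Returns ``(ref_coordinate, side, length)``
    tuples; no clips gives an empty list.
    """
    clips: List[Tuple[int, str, int]] = []
    ops = [op for op, _ in read.cigar]
    # leading S (possibly after H)
    i = 0
    if i < len(ops) and ops[i] == "H":
        i += 1
    if i < len(ops) and ops[i] == "S":
        clips.append((read.pos, "left", read.cigar[i][1]))
    j = len(ops) - 1
    if j >= 0 and ops[j] == "H":
        j -= 1
    if j > i and ops[j] == "S":
        clips.append((read.ref_end, "right", read.cigar[j][1]))
    return clips
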