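"""Retention heuristics: where qualities must be kept verbatim.

Six detectors flag loci (or whole reads) where any variant caller might be
confidently wrong: concordant soft clipping, excessive depth, low mapping
quality, more than two supported alleles, low-confidence consensus calls
and proximity to short tandem repeats.  Their outputs are merged into a
single :class:`RetentionMask` of half-open reference intervals plus a set
of whole-read retentions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple, Union

import numpy as np

from .consensus import CallArrays, CallerParams, GenotypeCall, NO_CALL_GENOTYPE
from .pileup import Entries, PileupColumn, ReadRecord

Interval = Tuple[int, int]

REASONS = ("softclip", "depth", "mapq", "alleles", "lowconf", "str")


@dataclass(frozen=True)
class HeuristicParams:
    clip_min_count: int = 3
    clip_min_fraction: float = 0.2
    depth_max: int = 400
    mapq_low: int = 10
    low_mapq_fraction: float = 0.5
    keep_colocated_high_mapq: bool = False
    max_alleles: int = 2
    str_unit_max: int = 4
    str_min_copies: int = 3
    pad: int = 10
    #: Detectors to run besides the always-on low-confidence one.
    enabled: Tuple[str, ...] = ("softclip", "depth", "mapq", "alleles", "str")


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Merge overlapping or adjacent half-open intervals, clipped at 0."""
    ivs = sorted((max(0, s), e) for s, e in intervals if e > s and e > 0)
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _merge_tagged(
    tagged: Iterable[Tuple[int, int, Set[str]]]
) -> List[Tuple[int, int, frozenset]]:
    ivs = sorted(
        ((max(0, s), e, set(t)) for s, e, t in tagged if e > s and e > 0),
        key=lambda x: (x[0], x[1]),
    )
    out: List[Tuple[int, int, Set[str]]] = []
    for s, e, t in ivs:
        if out and s <= out[-1][1]:
            out[-1][2].update(t)
            out[-1] = (out[-1][0], max(out[-1][1], e), out[-1][2])
        else:
            out.append((s, e, t))
    return [(s, e, frozenset(t)) for s, e, t in out]


@dataclass
class RetentionMask:
    """Merged, sorted retention intervals with reason tags + whole reads."""

    intervals: List[Tuple[int, int, frozenset]] = field(default_factory=list)
    whole_reads: Set[ReadRecord] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._starts = np.array([s for s, _, _ in self.intervals], dtype=np.int64)
        self._ends = np.array([e for _, e, _ in self.intervals], dtype=np.int64)

    @property
    def plain_intervals(self) -> List[Interval]:
        return [(s, e) for s, e, _ in self.intervals]

    def covers(self, pos: int) -> bool:
        i = int(np.searchsorted(self._starts, pos, side="right")) - 1
        return i >= 0 and pos < self._ends[i]

    def cover_positions(self, pos: np.ndarray) -> np.ndarray:
        """Boolean membership for an array of positions."""
        if not len(self._starts):
            return np.zeros(len(pos), dtype=bool)
        i = np.searchsorted(self._starts, pos, side="right") - 1
        ok = i >= 0
        out = np.zeros(len(pos), dtype=bool)
        out[ok] = pos[ok] < self._ends[i[ok]]
        return out

    def retains_read(self, read: ReadRecord) -> bool:
        return read in self.whole_reads

    def reason_counts(self) -> Dict[str, int]:
        c: Counter = Counter()
        for _, _, tags in self.intervals:
            for t in tags:
                c[t] += 1
        return dict(c)

    def covered_bases(self) -> int:
        return int(sum(e - s for s, e, _ in self.intervals))


ColumnsOrEntries = Union[Entries, Sequence[PileupColumn]]


def _depth_profile(x: ColumnsOrEntries) -> Tuple[int, np.ndarray]:
    if isinstance(x, Entries):
        return x.start, x.depth_profile()
    if not x:
        return 0, np.zeros(0, dtype=np.int64)
    start = x[0].pos
    depth = np.zeros(x[-1].pos + 1 - start, dtype=np.int64)
    for col in x:
        depth[col.pos - start] = col.depth
    return start, depth


def _base_count_grid(x: ColumnsOrEntries) -> Tuple[int, np.ndarray]:
    from .pileup import ALPHABET

    if isinstance(x, Entries):
        return x.start, x.base_count_grid()
    start, depth = _depth_profile(x)
    grid = np.zeros((len(depth), 6), dtype=np.int64)
    for col in x:
        for en in col.entries:
            grid[col.pos - start, ALPHABET.index(en.base)] += 1
    return start, grid


def _loci_to_intervals(flag: np.ndarray, start: int, pad: int) -> List[Interval]:
    """Padded intervals [pos-pad, pos+1+pad) for flagged loci, merged."""
    if not flag.any():
        return []
    d = np.diff(flag.astype(np.int8))
    run_starts = np.flatnonzero(d == 1) + 1
    run_ends = np.flatnonzero(d == -1) + 1
    if flag[0]:
        run_starts = np.concatenate(([0], run_starts))
    if flag[-1]:
        run_ends = np.concatenate((run_ends, [len(flag)]))
    return merge_intervals(
        (start + int(s) - pad, start + int(e) + pad)
        for s, e in zip(run_starts, run_ends)
    )


def detect_softclip_concordance(
    clips: Iterable[Tuple[int, str, int]],
    x: ColumnsOrEntries,
    params: HeuristicParams,
) -> List[Interval]:
    """Sites where many reads are clipped together (likely large insertion).

    A site fires when its pooled clip count reaches ``clip_min_count`` and
    at least ``clip_min_fraction`` of the reads spanning the site; the
    emitted interval is ``[site - pad, site + pad)``.
    """
    counts: Counter = Counter()
    for site, _side, _ln in clips:
        counts[site] += 1
    if not counts:
        return []
    start, depth = _depth_profile(x)
    n = len(depth)

    def near_depth(site: int) -> int:
        vals = [0]
        for p in (site - 1, site):
            i = p - start
            if 0 <= i < n:
                vals.append(int(depth[i]))
        return max(vals)

    out = []
    for site, cnt in counts.items():
        if cnt < params.clip_min_count:
            continue
        denom = max(near_depth(site), cnt, 1)
        if cnt / denom >= params.clip_min_fraction:
            out.append((site - params.pad, site + params.pad))
    return merge_intervals(out)


def detect_excess_depth(
    x: ColumnsOrEntries, params: HeuristicParams
) -> List[Interval]:
    """Loci deeper than ``depth_max`` (contamination / collapsed repeat)."""
    start, depth = _depth_profile(x)
    if not len(depth):
        return []
    return _loci_to_intervals(depth > params.depth_max, start, params.pad)


def detect_low_mapq(
    x: ColumnsOrEntries,
    reads: Sequence[ReadRecord],
    params: HeuristicParams,
) -> Tuple[List[Interval], Set[ReadRecord]]:
    """Low-MAPQ retention: whole reads, dense loci, optional colocated keeps."""
    whole: Set[ReadRecord] = {
        r for r in reads if r.eligible and r.mapq < params.mapq_low
    }
    if isinstance(x, Entries):
        start = x.start
        depth = x.depth_profile()
        idx = (x.pos - x.start).astype(np.int64)
        low = np.bincount(
            idx[x.mapq < params.mapq_low], minlength=x.end - x.start
        )
    else:
        start, depth = _depth_profile(x)
        low = np.zeros_like(depth)
        for col in x:
            low[col.pos - start] = sum(
                1 for en in col.entries if en.mapq < params.mapq_low
            )
    intervals: List[Interval] = []
    if len(depth):
        covered = depth > 0
        frac_hit = np.zeros(len(depth), dtype=bool)
        frac_hit[covered] = (
            low[covered] / depth[covered] >= params.low_mapq_fraction
        )
        intervals = _loci_to_intervals(frac_hit, start, params.pad)
    if params.keep_colocated_high_mapq and intervals:
        for r in reads:
            if not r.eligible or r.mapq < params.mapq_low:
                continue
            if any(r.pos < e and r.ref_end > s for s, e in intervals):
                whole.add(r)
    return intervals, whole


def detect_excess_alleles(
    x: ColumnsOrEntries, params: HeuristicParams
) -> List[Interval]:
    """Loci with more than ``max_alleles`` supported alleles.

    An allele (including '*') counts only with >=2 reads and >=10% of the
    column depth behind it, so isolated sequencing errors do not fire.
    """
    start, grid = _base_count_grid(x)
    if not len(grid):
        return []
    depth = grid.sum(axis=1)
    support = (grid[:, :5] >= 2) & (grid[:, :5] * 10 >= depth[:, None])
    n_alleles = support.sum(axis=1)
    return _loci_to_intervals(n_alleles > params.max_alleles, start, params.pad)


def detect_low_conf_calls(
    calls: Union[CallArrays, Sequence[GenotypeCall]],
    params: CallerParams,
    pad: int = 10,
) -> List[Interval]:
    """Covered loci whose adjusted call confidence misses the bar."""
    if isinstance(calls, CallArrays):
        flag = (calls.depth > 0) & (calls.phred_conf < params.conf_threshold)
        return _loci_to_intervals(flag, calls.start, pad)
    out = []
    for call in calls:
        low = call.genotype == NO_CALL_GENOTYPE or (
            call.phred_conf < params.conf_threshold
        )
        if call.depth > 0 and low:
            out.append((call.pos - pad, call.pos + 1 + pad))
    return merge_intervals(out)


def find_tandem_tracts(
    seq: str, unit_max: int, min_copies: int
) -> List[Interval]:
    """Maximal tandem tracts (unit length <= unit_max) with enough copies.

    A tract qualifies when it contains at least ``min_copies`` complete
    copies of its unit; the emitted span covers the whole periodic stretch
    including any trailing partial copy.  Only A/C/G/T participate.
    """
    n = len(seq)
    if n == 0:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    acgt = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    tracts: List[Interval] = []
    for u in range(1, unit_max + 1):
        if n <= u:
            break
        eq = (arr[:-u] == arr[u:]) & acgt[:-u] & acgt[u:]
        if not eq.any():
            continue
        d = np.diff(eq.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if eq[0]:
            starts = np.concatenate(([0], starts))
        if eq[-1]:
            ends = np.concatenate((ends, [len(eq)]))
        for s, e in zip(starts, ends):
            span = int(e) - int(s) + u  # periodic region length
            if span // u >= min_copies:
                tracts.append((int(s), int(s) + span))
    return sorted(set(tracts))


def detect_str(
    consensus: str,
    start: int,
    params: HeuristicParams,
    indel_spans: Sequence[Interval] = (),
) -> List[Interval]:
    """Short-tandem-repeat tracts in the window consensus, padded.

    Tracts overlapped by a read's indel are extended to cover the full
    indel span so the whole wobbly region keeps its qualities.
    """
    tracts = find_tandem_tracts(consensus, params.str_unit_max, params.str_min_copies)
    out: List[Interval] = []
    for s, e in tracts:
        lo, hi = start + s - params.pad, start + e + params.pad
        for ds, de in indel_spans:
            if ds < hi and de > lo:
                lo, hi = min(lo, ds), max(hi, de)
        out.append((lo, hi))
    return merge_intervals(out)


def assemble_mask(
    by_reason: Mapping[str, Iterable[Interval]],
    whole_reads: Iterable[ReadRecord] = (),
) -> RetentionMask:
    """Union all detector outputs into one merged, tagged mask."""
    tagged = [
        (s, e, {reason})
        for reason, ivs in sorted(by_reason.items())
        for s, e in ivs
    ]
    return RetentionMask(
        intervals=_merge_tagged(tagged), whole_reads=set(whole_reads)
    )
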