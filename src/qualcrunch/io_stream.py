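"""Streaming window-by-window processing of coordinate-sorted SAM/BAM.

Reads are grouped into fixed-size windows by start position; each window's
detectors see ``overlap`` bases of context on either side, so a windowed
run and a monolithic run produce identical output whenever the window size
comfortably exceeds twice the read length plus padding.  Every record is
emitted exactly once, in input order; ineligible records (unmapped,
secondary, supplementary, duplicate, QC-fail) pass through byte-identical.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from . import __version__
from .consensus import CallerParams, call_entries
from .heuristics import (
    HeuristicParams,
    assemble_mask,
    detect_excess_alleles,
    detect_excess_depth,
    detect_low_conf_calls,
    detect_low_mapq,
    detect_softclip_concordance,
    detect_str,
)
from .pileup import (
    DEFAULT_MAPQ_SUBSTITUTE,
    ReadRecord,
    expand_reads,
    softclip_positions,
)
from .rewrite import QualityPolicy, rewrite_read_ex

logger = logging.getLogger("qualcrunch")

DEFAULT_WINDOW = 10_000
DEFAULT_OVERLAP = 1_000

_CIGAR_OPS = "MIDNSHP=X"


@dataclass
class Window:
    """One processing unit: records to emit plus surrounding context."""

    ref_id: int
    start: int
    end: int
    records: List[Tuple[pysam.AlignedSegment, Optional[ReadRecord]]]
    context: List[ReadRecord]


@dataclass
class CompressionStats:
    reads_in: int = 0
    reads_out: int = 0
    bases: int = 0
    kept_bases: int = 0
    qual_counts_in: np.ndarray = field(
        default_factory=lambda: np.zeros(94, dtype=np.int64)
    )
    qual_counts_out: np.ndarray = field(
        default_factory=lambda: np.zeros(94, dtype=np.int64)
    )
    reason_intervals: Dict[str, int] = field(default_factory=dict)
    windows: int = 0

    @property
    def retained_fraction(self) -> float:
        return self.kept_bases / self.bases if self.bases else 0.0

    def add_reasons(self, counts: Dict[str, int]) -> None:
        for k, v in counts.items():
            self.reason_intervals[k] = self.reason_intervals.get(k, 0) + v


def to_readrecord(rec: pysam.AlignedSegment) -> Optional[ReadRecord]:
    """Convert an eligible pysam record; None means pass-through."""
    if (
        rec.is_unmapped
        or rec.is_secondary
        or rec.is_supplementary
        or rec.is_duplicate
        or rec.is_qcfail
    ):
        return None
    if rec.query_sequence is None or rec.query_qualities is None:
        return None
    cigar = [(_CIGAR_OPS[op], ln) for op, ln in rec.cigartuples or []]
    return ReadRecord(
        name=rec.query_name or "",
        ref_id=rec.reference_id,
        pos=rec.reference_start,
        cigar=cigar,
        seq=rec.query_sequence,
        qual=np.asarray(rec.query_qualities, dtype=np.int16),
        mapq=rec.mapping_quality,
        flags=rec.flag,
    )


def _iter_windows(
    af: pysam.AlignmentFile, window_size: int, overlap: int
) -> Iterator[Window]:
    if window_size <= 2 * overlap:
        raise ValueError("window_size must exceed 2 * overlap")
    emit_q: deque = deque()  # (rec, rr, pos)
    ctx: deque = deque()  # eligible ReadRecords still possibly needed
    win_ext: Dict[int, int] = {}  # window index -> max ref_end of its reads
    cur_tid = None
    last_pos = -1
    tail: List[pysam.AlignedSegment] = []

    def pending_windows(threshold: Optional[int]) -> Iterator[Window]:
        nonlocal ctx
        while emit_q:
            k = emit_q[0][2] // window_size
            wstart, wend = k * window_size, (k + 1) * window_size
            ext_needed = max(wend + overlap, win_ext.get(k, 0) + 1)
            if threshold is not None and threshold < ext_needed:
                return
            batch = []
            while emit_q and emit_q[0][2] < wend:
                rec, rr, _ = emit_q.popleft()
                batch.append((rec, rr))
            win_ext.pop(k, None)
            ctx_reads = [
                r for r in ctx if r.ref_end > wstart - overlap and r.pos < ext_needed
            ]
            yield Window(
                ref_id=cur_tid if cur_tid is not None else -1,
                start=wstart,
                end=wend,
                records=batch,
                context=ctx_reads,
            )
            ctx = deque(r for r in ctx if r.ref_end > wend - overlap)

    for rec in af:
        if rec.reference_id < 0 or rec.reference_start < 0:
            tail.append(rec)
            continue
        tid, pos = rec.reference_id, rec.reference_start
        if tid != cur_tid:
            if cur_tid is not None and tid < cur_tid:
                raise ValueError(
                    f"input not coordinate-sorted at read {rec.query_name!r}"
                )
            yield from pending_windows(None)
            win_ext.clear()
            cur_tid, last_pos = tid, -1
        if pos < last_pos:
            raise ValueError(
                f"input not coordinate-sorted at read {rec.query_name!r} "
                f"(pos {pos} after {last_pos})"
            )
        last_pos = pos
        yield from pending_windows(pos)
        rr = to_readrecord(rec)
        emit_q.append((rec, rr, pos))
        if rr is not None:
            ctx.append(rr)
            k = pos // window_size
            if rr.ref_end > win_ext.get(k, 0):
                win_ext[k] = rr.ref_end
    yield from pending_windows(None)
    if tail:
        yield Window(ref_id=-1, start=-1, end=-1, records=[(r, None) for r in tail],
                     context=[])


def stream_windows(
    path,
    window_size: int = DEFAULT_WINDOW,
    overlap: int = DEFAULT_OVERLAP,
) -> Iterator[Window]:
    """Yield :class:`Window` objects from a coordinate-sorted SAM/BAM/CRAM."""
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        yield from _iter_windows(af, window_size, overlap)


def _write_mode(path) -> str:
    s = str(path)
    if s.endswith(".bam"):
        return "wb"
    if s.endswith(".cram"):
        return "wc"
    return "wh"


class RecordWriter:
    """Write records with optional identifier/aux dropping and a @PG line."""

    def __init__(
        self,
        path,
        header: dict,
        drop_names: bool = False,
        drop_aux: Sequence[str] = (),
        command: Optional[str] = None,
    ):
        header = dict(header)
        pg = list(header.get("PG", []))
        used = {e.get("ID") for e in pg}
        pg_id = "qualcrunch"
        n = 1
        while pg_id in used:
            n += 1
            pg_id = f"qualcrunch.{n}"
        entry = {"ID": pg_id, "PN": "qualcrunch", "VN": __version__}
        if pg:
            entry["PP"] = pg[-1].get("ID")
        entry["CL"] = command or "qualcrunch"
        header["PG"] = pg + [entry]
        self._out = pysam.AlignmentFile(str(path), _write_mode(path), header=header)
        self._drop_names = drop_names
        self._drop_aux = tuple(drop_aux)
        self._name_map: Dict[str, str] = {}

    def write(self, rec: pysam.AlignedSegment) -> None:
        if self._drop_names:
            name = rec.query_name or ""
            new = self._name_map.get(name)
            if new is None:
                new = f"r{len(self._name_map)}"
                self._name_map[name] = new
            rec.query_name = new
        for tag in self._drop_aux:
            if rec.has_tag(tag):
                rec.set_tag(tag, None)
        self._out.write(rec)

    def close(self) -> None:
        self._out.close()

    def __enter__(self) -> "RecordWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_records(
    records: Iterable[pysam.AlignedSegment],
    path,
    header: dict,
    drop_names: bool = False,
    drop_aux: Sequence[str] = (),
    command: Optional[str] = None,
) -> None:
    """Write an iterable of records to a SAM/BAM file."""
    with RecordWriter(path, header, drop_names, drop_aux, command) as w:
        for rec in records:
            w.write(rec)


def _process_window(
    win: Window,
    policy: QualityPolicy,
    hparams: HeuristicParams,
    cparams: CallerParams,
    overlap: int,
    writer: RecordWriter,
    stats: CompressionStats,
) -> None:
    eligible_emitted = [rr for _, rr in win.records if rr is not None]
    if not eligible_emitted:
        for rec, _ in win.records:
            writer.write(rec)
            stats.reads_in += 1
            stats.reads_out += 1
        return
    ext_start = max(0, win.start - overlap)
    # bound the span by the data so huge nominal windows stay cheap
    data_end = max(r.ref_end for r in win.context)
    ext_end = max(
        min(win.end + overlap, data_end),
        max(rr.ref_end for rr in eligible_emitted) + 1,
    )
    entries = expand_reads(win.context, (ext_start, ext_end))
    calls = call_entries(entries, cparams)

    by_reason: Dict[str, List[Tuple[int, int]]] = {}
    whole: set = set()
    on = set(hparams.enabled)
    if "softclip" in on:
        clips = [c for r in win.context for c in softclip_positions(r)]
        by_reason["softclip"] = detect_softclip_concordance(clips, entries, hparams)
    if "depth" in on:
        by_reason["depth"] = detect_excess_depth(entries, hparams)
    if "mapq" in on:
        ivs, whole = detect_low_mapq(entries, win.context, hparams)
        by_reason["mapq"] = ivs
    if "alleles" in on:
        by_reason["alleles"] = detect_excess_alleles(entries, hparams)
    # The low-confidence detector is the construction guaranteeing that
    # every unconfident covered locus is masked; it always runs.
    by_reason["lowconf"] = detect_low_conf_calls(calls, cparams, hparams.pad)
    if "str" in on:
        by_reason["str"] = detect_str(
            calls.consensus_string(), ext_start, hparams, entries.indel_spans()
        )
    mask = assemble_mask(by_reason, whole)
    stats.add_reasons(mask.reason_counts())
    stats.windows += 1
    if logger.isEnabledFor(logging.DEBUG):
        logger.debug(
            "window %s:%d-%d intervals=%s whole_reads=%d",
            win.ref_id, win.start, win.end, mask.reason_counts(), len(mask.whole_reads),
        )

    for rec, rr in win.records:
        stats.reads_in += 1
        if rr is None:
            writer.write(rec)
            stats.reads_out += 1
            continue
        new, kept = rewrite_read_ex(rr, mask, calls, policy)
        stats.bases += len(new.qual)
        stats.kept_bases += int(kept.sum())
        stats.qual_counts_in += np.bincount(rr.qual, minlength=94)
        stats.qual_counts_out += np.bincount(new.qual, minlength=94)
        rec.query_qualities = [int(q) for q in new.qual]
        writer.write(rec)
        stats.reads_out += 1


def compress(
    in_path,
    out_path,
    policy: QualityPolicy,
    hparams: HeuristicParams,
    cparams: CallerParams,
    window_size: int = DEFAULT_WINDOW,
    overlap: int = DEFAULT_OVERLAP,
    drop_names: bool = False,
    drop_aux: Sequence[str] = (),
    command: Optional[str] = None,
) -> CompressionStats:
    """Run the full lossy-compression pipeline file-to-file."""
    stats = CompressionStats()
    with pysam.AlignmentFile(str(in_path), check_sq=False) as af:
        header = af.header.to_dict()
        with RecordWriter(
            out_path, header, drop_names=drop_names, drop_aux=drop_aux,
            command=command,
        ) as writer:
            for win in _iter_windows(af, window_size, overlap):
                _process_window(
                    win, policy, hparams, cparams, overlap, writer, stats
                )
    return stats
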