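"""Quality rewriting: spend the quality budget.

Given per-locus consensus calls and a retention mask, each read's quality
string is rewritten: masked or whole-retained positions stay verbatim,
bases agreeing with a confident call become one constant high value, and
everything else (disagreements, unconfident loci, soft clips, insertions)
follows the configured disagree mode - constant low, quantized, or kept.
Kept stretches can optionally be smoothed with the P-block scheme.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace
from typing import List, Mapping, Sequence, Tuple, Union

import numpy as np

from .consensus import CallArrays, CallSource, GenotypeCall, MappingCalls
from .heuristics import RetentionMask
from .pileup import ReadRecord, encode_bases

QUAL_MAX = 93

#: 8-bin Illumina-style quantization: (lo, hi, representative), inclusive.
#: Representatives sit at the bin floor so quantizing a disagreeing base can
#: never *raise* its quality — raising it would strengthen the pessimistic
#: mismatch penalty and could flip an unmasked confident call.
DEFAULT_QUANT_BINS: Tuple[Tuple[int, int, int], ...] = (
    (0, 1, 0),
    (2, 9, 2),
    (10, 19, 10),
    (20, 24, 20),
    (25, 29, 25),
    (30, 34, 30),
    (35, 39, 35),
    (40, 93, 40),
)

IDENTITY_BINS: Tuple[Tuple[int, int, int], ...] = tuple(
    (q, q, q) for q in range(QUAL_MAX + 1)
)


@dataclass(frozen=True)
class QualityPolicy:
    qual_high: int = 40
    disagree_mode: str = "low"  # one of low | quantize | keep
    qual_low: int = 10
    quant_bins: Tuple[Tuple[int, int, int], ...] = DEFAULT_QUANT_BINS
    pblock_p: int = 0  # 0 = off
    preset_level: int = 1

    def __post_init__(self) -> None:
        if self.disagree_mode not in ("low", "quantize", "keep"):
            raise ValueError(f"bad disagree_mode {self.disagree_mode!r}")
        if not 0 <= self.qual_high <= QUAL_MAX or not 0 <= self.qual_low <= QUAL_MAX:
            raise ValueError("qual_high/qual_low must lie in [0, 93]")


def quant_lut(bins: Sequence[Tuple[int, int, int]]) -> np.ndarray:
    """Lookup table for a bin set; the bins must partition [0, 93]."""
    return _quant_lut_cached(tuple(tuple(b) for b in bins))


@functools.lru_cache(maxsize=32)
def _quant_lut_cached(bins: Tuple[Tuple[int, int, int], ...]) -> np.ndarray:
    lut = np.full(QUAL_MAX + 1, -1, dtype=np.int16)
    for lo, hi, rep in bins:
        if lo > hi or not (0 <= lo and hi <= QUAL_MAX) or not 0 <= rep <= QUAL_MAX:
            raise ValueError(f"bad quantizer bin {(lo, hi, rep)}")
        if (lut[lo : hi + 1] != -1).any():
            raise ValueError("quantizer bins overlap")
        lut[lo : hi + 1] = rep
    if (lut == -1).any():
        raise ValueError("quantizer bins do not cover [0, 93]")
    return lut


def quantize(
    quals: Sequence[int], bins: Sequence[Tuple[int, int, int]] = DEFAULT_QUANT_BINS
) -> np.ndarray:
    """Map each quality onto its bin representative (idempotent)."""
    q = np.asarray(quals, dtype=np.int64)
    if len(q) and (q.min() < 0 or q.max() > QUAL_MAX):
        raise ValueError("quality value outside [0, 93]")
    return quant_lut(bins)[q].astype(np.int16)


def pblock_smooth(quals: Sequence[int], p: int) -> np.ndarray:
    """Greedy horizontal smoothing: each block's values move to a single
    representative no further than ``p`` from any original value.

    Blocks grow left to right while (max - min) of the original values
    stays <= 2p; on close every position becomes floor((max+min)/2).
    ``p=0`` is the identity.
    """
    if p < 0:
        raise ValueError("p must be >= 0")
    q = np.asarray(quals, dtype=np.int16).copy()
    if p == 0 or len(q) == 0:
        return q
    n = len(q)
    i = 0
    while i < n:
        mn = mx = int(q[i])
        j = i + 1
        while j < n:
            v = int(q[j])
            nmn = v if v < mn else mn
            nmx = v if v > mx else mx
            if nmx - nmn > 2 * p:
                break
            mn, mx = nmn, nmx
            j += 1
        q[i:j] = (mn + mx) // 2
        i = j
    return q


def _as_call_source(
    calls: Union[CallArrays, MappingCalls, Mapping[int, GenotypeCall]],
    conf_threshold: float,
) -> CallSource:
    if isinstance(calls, (CallArrays, MappingCalls)):
        return calls
    return MappingCalls(calls, conf_threshold)


def rewrite_read(
    read: ReadRecord,
    mask: RetentionMask,
    calls: Union[CallArrays, MappingCalls, Mapping[int, GenotypeCall]],
    policy: QualityPolicy,
    conf_threshold: float = 30.0,
) -> ReadRecord:
    """Rewritten copy of ``read``; everything but QUAL is untouched."""
    new, _ = rewrite_read_ex(read, mask, calls, policy, conf_threshold)
    return new


def rewrite_read_ex(
    read: ReadRecord,
    mask: RetentionMask,
    calls: Union[CallArrays, MappingCalls, Mapping[int, GenotypeCall]],
    policy: QualityPolicy,
    conf_threshold: float = 30.0,
) -> Tuple[ReadRecord, np.ndarray]:
    """As :func:`rewrite_read` but also returns the verbatim-kept flags.

    Raises ``LookupError`` when a covered locus has no consensus call
    (a pipeline bug, never a data condition).
    """
    out = read.qual.astype(np.int16).copy()
    kept = np.zeros(len(out), dtype=bool)
    if mask.retains_read(read):
        kept[:] = True
        if policy.pblock_p > 0:
            out = pblock_smooth(out, policy.pblock_p)
        return replace_qual(read, out), kept

    source = _as_call_source(calls, conf_threshold)
    lut = quant_lut(policy.quant_bins) if policy.disagree_mode == "quantize" else None
    bases = encode_bases(read.seq)

    def apply_disagree(qidx: np.ndarray) -> None:
        if len(qidx) == 0:
            return
        if policy.disagree_mode == "low":
            out[qidx] = policy.qual_low
        elif policy.disagree_mode == "quantize":
            out[qidx] = lut[read.qual[qidx]]
        else:  # keep
            kept[qidx] = True

    def boundary_masked(site: int) -> bool:
        return mask.covers(site) or mask.covers(site - 1)

    rpos = read.pos
    q = 0
    for op, ln in read.cigar:
        if op in "M=X":
            pos = np.arange(rpos, rpos + ln, dtype=np.int64)
            qidx = np.arange(q, q + ln)
            in_mask = mask.cover_positions(pos)
            g1, g2, conf = source.lookup(pos, owner=read.name)
            agree = conf & ((bases[qidx] == g1) | (bases[qidx] == g2))
            kept[qidx[in_mask]] = True
            hi = ~in_mask & agree
            out[qidx[hi]] = policy.qual_high
            apply_disagree(qidx[~in_mask & ~agree])
            rpos += ln
            q += ln
        elif op == "I":
            qidx = np.arange(q, q + ln)
            if boundary_masked(rpos):
                kept[qidx] = True
            else:
                apply_disagree(qidx)
            q += ln
        elif op == "S":
            qidx = np.arange(q, q + ln)
            if boundary_masked(rpos):
                kept[qidx] = True
            else:
                apply_disagree(qidx)
            q += ln
        elif op == "D" or op == "N":
            rpos += ln
        # H, P: nothing stored.

    if policy.pblock_p > 0 and kept.any():
        d = np.diff(kept.astype(np.int8))
        run_starts = list(np.flatnonzero(d == 1) + 1)
        run_ends = list(np.flatnonzero(d == -1) + 1)
        if kept[0]:
            run_starts.insert(0, 0)
        if kept[-1]:
            run_ends.append(len(kept))
        for s, e in zip(run_starts, run_ends):
            out[s:e] = pblock_smooth(out[s:e], policy.pblock_p)
    return replace_qual(read, out), kept


def replace_qual(read: ReadRecord, qual: np.ndarray) -> ReadRecord:
    return replace(read, qual=np.asarray(qual, dtype=np.int16))
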