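"""Naive, deliberately pessimistic diploid consensus caller.

Per pileup column the most likely homozygous or heterozygous genotype over
the five-letter alphabet {A, C, G, T, *} is selected by exhaustive scoring
of the 15 possible genotypes under a flat prior, then the Phred-scaled
confidence is reduced by the evidence of every entry that contradicts the
chosen genotype.  The intent is not to be a good caller but to flag every
locus where some downstream caller might hesitate.

Emission model, per entry with effective error probability ``e`` (from the
capped minimum of base quality and mapping quality):

* homozygote {g,g}:   P(b) = 1-e          if b == g, else e/4
* heterozygote {g,h}: P(b) = (1-e)/2+e/8  if b in {g,h}, else e/4

'N' entries carry no information and are excluded from the likelihood but
still count toward depth and toward the pessimistic penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Mapping, Sequence, Tuple, Union

import numpy as np

from .pileup import ALPHABET, N, STAR, Entries, PileupColumn, encode_bases

# Genotype table: homozygotes first, then heterozygotes in lexicographic
# order.  np.argmax returns the first maximum, so this ordering *is* the
# tie-break rule (prefer homozygous, then A<C<G<T<*).
GENOTYPES: List[Tuple[int, int]] = [(b, b) for b in range(5)] + [
    (i, j) for i in range(5) for j in range(i + 1, 5)
]
_G1 = np.array([g for g, _ in GENOTYPES])
_G2 = np.array([h for _, h in GENOTYPES])
_IS_HET = _G1 != _G2

CONF_CAP = 99.0
_E_MAX = 0.75  # guards log(1-e) when an effective quality is ~0
_LN10 = math.log(10.0)


@dataclass(frozen=True)
class CallerParams:
    """Knobs of the consensus caller.

    conf_threshold
        Phred bar a call must meet to count as confident (inclusive).
    max_phred_cap
        Ceiling on the per-entry effective quality.
    mapq_floor
        Mapping qualities below this are raised to it, so a MAPQ-0 read
        still contributes (vanishingly weak) evidence instead of a
        zero-probability pathology.
    """

    conf_threshold: float = 30.0
    max_phred_cap: int = 40
    mapq_floor: int = 3


@dataclass(frozen=True)
class GenotypeCall:
    pos: int
    genotype: Tuple[str, str]
    phred_conf: float
    raw_conf: float
    allele_count: int
    depth: int


NO_CALL_GENOTYPE = ("N", "N")


def _effective_error(
    qual: np.ndarray, mapq: np.ndarray, params: CallerParams
) -> np.ndarray:
    eff = np.minimum(
        np.minimum(qual, np.maximum(mapq, params.mapq_floor)), params.max_phred_cap
    ).astype(np.float64)
    e = np.power(10.0, -eff / 10.0)
    return np.minimum(e, _E_MAX)


@dataclass
class CallArrays:
    """Vectorised per-locus calls over a half-open span.

    ``g1``/``g2`` are base codes (5 == no call), confidences are floats and
    ``confident`` was evaluated against the params used at call time.
    """

    start: int
    end: int
    g1: np.ndarray
    g2: np.ndarray
    raw_conf: np.ndarray
    phred_conf: np.ndarray
    depth: np.ndarray
    allele_count: np.ndarray
    confident: np.ndarray

    def get(self, pos: int) -> GenotypeCall:
        i = pos - self.start
        if i < 0 or i >= self.end - self.start:
            raise KeyError(pos)
        g1, g2 = int(self.g1[i]), int(self.g2[i])
        return GenotypeCall(
            pos=pos,
            genotype=(ALPHABET[g1], ALPHABET[g2]),
            phred_conf=float(self.phred_conf[i]),
            raw_conf=float(self.raw_conf[i]),
            allele_count=int(self.allele_count[i]),
            depth=int(self.depth[i]),
        )

    def lookup(
        self, pos: np.ndarray, owner: str = "?"
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(g1, g2, confident) for an array of positions; missing -> error."""
        idx = pos - self.start
        if len(idx) and (idx.min() < 0 or idx.max() >= self.end - self.start):
            bad = pos[(idx < 0) | (idx >= self.end - self.start)][0]
            raise LookupError(
                f"no consensus call at position {int(bad)} (needed by {owner})"
            )
        return self.g1[idx], self.g2[idx], self.confident[idx]

    def consensus_string(self) -> str:
        """First allele per locus; uncovered loci become 'N'."""
        return "".join(ALPHABET[c] for c in self.g1)


def call_entries(entries: Entries, params: CallerParams) -> CallArrays:
    """Score all 15 genotypes at every locus of ``entries`` in one pass."""
    start, end = entries.start, entries.end
    npos = end - start
    idx = (entries.pos - start).astype(np.int64)
    base = entries.base.astype(np.int64)
    valid = base != N

    e = _effective_error(entries.qual, entries.mapq, params)
    log_e4 = np.log(e / 4.0)
    l_hom = np.log1p(-e)
    l_het = np.log((1.0 - e) / 2.0 + e / 8.0)

    flat = idx * 6 + base
    S = np.bincount(idx[valid], weights=log_e4[valid], minlength=npos)
    A_grid = np.bincount(
        flat[valid], weights=(l_hom - log_e4)[valid], minlength=npos * 6
    ).reshape(npos, 6)
    H_grid = np.bincount(
        flat[valid], weights=(l_het - log_e4)[valid], minlength=npos * 6
    ).reshape(npos, 6)
    # Penalty weights: min(base qual, mapping qual), uncapped; N included.
    w = np.minimum(entries.qual, entries.mapq).astype(np.float64)
    W_grid = np.bincount(flat, weights=w, minlength=npos * 6).reshape(npos, 6)
    counts = np.bincount(flat, minlength=npos * 6).reshape(npos, 6)

    depth = counts.sum(axis=1)
    allele_count = (counts[:, :5] > 0).sum(axis=1)

    logL = S[:, None] + np.where(
        _IS_HET[None, :],
        H_grid[:, _G1] + H_grid[:, _G2],
        A_grid[:, _G1],
    )
    best = np.argmax(logL, axis=1)
    rows = np.arange(npos)
    m = logL[rows, best]
    shifted = np.exp(logL - m[:, None])
    shifted[rows, best] = 0.0  # summed separately to dodge cancellation
    rest = shifted.sum(axis=1)
    ssum = rest + 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = -10.0 * np.log10(rest / ssum)
    raw = np.where(rest <= 0, CONF_CAP, np.minimum(raw, CONF_CAP))
    raw = np.maximum(raw, 0.0)

    w_tot = W_grid.sum(axis=1)
    pen = w_tot - W_grid[rows, _G1[best]]
    pen = pen - np.where(_IS_HET[best], W_grid[rows, _G2[best]], 0.0)
    phred = np.maximum(raw - pen, 0.0)

    has_evidence = np.bincount(idx[valid], minlength=npos) > 0
    g1 = np.where(has_evidence, _G1[best], N).astype(np.uint8)
    g2 = np.where(has_evidence, _G2[best], N).astype(np.uint8)
    raw = np.where(has_evidence, raw, 0.0)
    phred = np.where(has_evidence, phred, 0.0)
    confident = has_evidence & (phred >= params.conf_threshold)
    return CallArrays(
        start=start,
        end=end,
        g1=g1,
        g2=g2,
        raw_conf=raw,
        phred_conf=phred,
        depth=depth.astype(np.int32),
        allele_count=allele_count.astype(np.int16),
        confident=confident,
    )


def _column_entries(col: PileupColumn) -> Entries:
    base = encode_bases("".join(en.base for en in col.entries))
    qual = np.array([en.qual for en in col.entries], dtype=np.int16)
    mapq = np.array([en.mapq for en in col.entries], dtype=np.int16)
    n = len(col.entries)
    return Entries(
        start=col.pos,
        end=col.pos + 1,
        pos=np.full(n, col.pos, dtype=np.int64),
        base=base,
        qual=qual,
        mapq=mapq,
        read_index=np.arange(n, dtype=np.int32),
        qpos=np.zeros(n, dtype=np.int32),
        reads=[en.read for en in col.entries],
        insertions=[],
        deletions=[],
    )


def genotype_call(col: PileupColumn, params: CallerParams) -> GenotypeCall:
    """Most likely diploid genotype for one column, pre-adjustment.

    The returned ``phred_conf`` equals ``raw_conf``; apply
    :func:`pessimistic_adjust` to obtain the reduced confidence.  An empty
    column yields the ('N','N') sentinel at confidence 0.
    """
    if not col.entries:
        return GenotypeCall(
            pos=col.pos,
            genotype=NO_CALL_GENOTYPE,
            phred_conf=0.0,
            raw_conf=0.0,
            allele_count=0,
            depth=0,
        )
    arr = call_entries(_column_entries(col), params)
    call = arr.get(col.pos)
    return replace(call, phred_conf=call.raw_conf)


def mismatch_penalty(col: PileupColumn, genotype: Tuple[str, str]) -> float:
    """Sum of min(qual, mapq) over entries whose base is not in ``genotype``."""
    return float(
        sum(min(en.qual, en.mapq) for en in col.entries if en.base not in genotype)
    )


def pessimistic_adjust(call: GenotypeCall, col: PileupColumn) -> GenotypeCall:
    """Reduce confidence by the evidence of non-matching entries.

    ``phred_conf = max(0, raw_conf - penalty)``; idempotent because the
    adjustment always starts from ``raw_conf``.
    """
    if call.genotype == NO_CALL_GENOTYPE:
        return replace(call, phred_conf=0.0)
    pen = mismatch_penalty(col, call.genotype)
    return replace(call, phred_conf=max(0.0, call.raw_conf - pen))


def is_confident(call: GenotypeCall, params: CallerParams) -> bool:
    """True iff the adjusted confidence meets the bar (inclusive)."""
    if call.genotype == NO_CALL_GENOTYPE:
        return False
    return call.phred_conf >= params.conf_threshold


class MappingCalls:
    """Adapter exposing a {pos: GenotypeCall} mapping as call arrays."""

    def __init__(self, calls: Mapping[int, GenotypeCall], conf_threshold: float):
        self._calls = dict(calls)
        self._threshold = conf_threshold

    def lookup(
        self, pos: np.ndarray, owner: str = "?"
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        g1 = np.empty(len(pos), dtype=np.uint8)
        g2 = np.empty(len(pos), dtype=np.uint8)
        conf = np.empty(len(pos), dtype=bool)
        for k, p in enumerate(pos):
            call = self._calls.get(int(p))
            if call is None:
                raise LookupError(
                    f"no consensus call at position {int(p)} (needed by {owner})"
                )
            g1[k] = ALPHABET.index(call.genotype[0])
            g2[k] = ALPHABET.index(call.genotype[1])
            conf[k] = (
                call.genotype != NO_CALL_GENOTYPE
                and call.phred_conf >= self._threshold
            )
        return g1, g2, conf


CallSource = Union[CallArrays, MappingCalls]
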