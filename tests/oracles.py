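"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in plain Python (loops, math
module) so it shares no code path with the vectorised package internals.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Sequence, Tuple

GENOTYPES = [(a, a) for a in "ACGT*"] + [
    ("ACGT*"[i], "ACGT*"[j]) for i in range(5) for j in range(i + 1, 5)
]

E_MAX = 0.75


def oracle_call(
    entries: Sequence[Tuple[str, int, int]],
    cap: int = 40,
    mapq_floor: int = 3,
) -> Dict[str, object]:
    """Enumerate all 15 diploid genotypes for one column.

    ``entries`` are (base, qual, effective_mapq) triples.  Returns genotype,
    per-genotype log-likelihoods, raw confidence, pessimistic penalty and
    adjusted confidence, mirroring the documented emission model.
    """
    logls: List[float] = []
    for g1, g2 in GENOTYPES:
        total = 0.0
        for base, qual, mapq in entries:
            if base == "N":
                continue
            eff = min(qual, max(mapq, mapq_floor), cap)
            e = min(10.0 ** (-eff / 10.0), E_MAX)
            if g1 == g2:
                p = (1.0 - e) if base == g1 else e / 4.0
            else:
                p = ((1.0 - e) / 2.0 + e / 8.0) if base in (g1, g2) else e / 4.0
            total += math.log(p)
        logls.append(total)

    best = 0
    for i in range(1, 15):
        if logls[i] > logls[best]:
            best = i
    has_evidence = any(b != "N" for b, _, _ in entries)
    if not has_evidence:
        return {
            "genotype": ("N", "N"),
            "logls": logls,
            "raw_conf": 0.0,
            "penalty": 0.0,
            "phred_conf": 0.0,
        }
    m = max(logls)
    rest = sum(math.exp(l - m) for i, l in enumerate(logls) if i != best)
    total_w = rest + math.exp(logls[best] - m)
    if rest <= 0:
        raw = 99.0
    else:
        raw = min(99.0, -10.0 * math.log10(rest / total_w))
    raw = max(raw, 0.0)
    genotype = GENOTYPES[best]
    penalty = float(
        sum(min(q, mq) for b, q, mq in entries if b not in genotype)
    )
    return {
        "genotype": genotype,
        "logls": logls,
        "raw_conf": raw,
        "penalty": penalty,
        "phred_conf": max(0.0, raw - penalty),
    }


def oracle_pblock(vals: Sequence[int], p: int) -> Tuple[List[int], List[Tuple[int, int]]]:
    """Greedy P-block smoothing; returns (values, block boundaries)."""
    out = list(vals)
    blocks = []
    i = 0
    n = len(vals)
    while i < n:
        lo = hi = vals[i]
        j = i + 1
        while j < n:
            lo2 = min(lo, vals[j])
            hi2 = max(hi, vals[j])
            if hi2 - lo2 > 2 * p:
                break
            lo, hi = lo2, hi2
            j += 1
        rep = (lo + hi) // 2
        for k in range(i, j):
            out[k] = rep
        blocks.append((i, j))
        i = j
    return out, blocks


def oracle_merge(
    tagged: Iterable[Tuple[int, int, str]], limit: int
) -> List[Tuple[int, int, frozenset]]:
    """Paint-and-scan interval merge over a bounded coordinate range."""
    paint: List[set] = [set() for _ in range(limit)]
    for s, e, tag in tagged:
        for p in range(max(0, s), min(limit, e)):
            paint[p].add(tag)
    out = []
    p = 0
    while p < limit:
        if not paint[p]:
            p += 1
            continue
        start = p
        tags: set = set()
        while p < limit and paint[p]:
            tags |= paint[p]
            p += 1
        out.append((start, p, frozenset(tags)))
    return out


def oracle_coverage(
    reads, span: Tuple[int, int]
) -> Dict[int, int]:
    """Per-locus count of reads whose alignment (M/=/X/D) spans the locus."""
    start, end = span
    depth = {p: 0 for p in range(start, end)}
    for r in reads:
        if not r.eligible:
            continue
        rpos = r.pos
        for op, ln in r.cigar:
            if op in "M=XD":
                for p in range(rpos, rpos + ln):
                    if start <= p < end:
                        depth[p] += 1
                rpos += ln
            elif op == "N":
                rpos += ln
    return depth


def oracle_ref_walk(read) -> List[Tuple[int, str, int]]:
    """Soft-clip sites by walking the CIGAR accumulating reference ops."""
    out = []
    ref = read.pos
    seen_aligned = False
    for op, ln in read.cigar:
        if op == "S":
            out.append((ref, "right" if seen_aligned else "left", ln))
        elif op in "MDN=X":
            ref += ln
            seen_aligned = True
    return out


def oracle_tandem(seq: str, unit_max: int, min_copies: int) -> List[Tuple[int, int]]:
    """Quadratic scan for maximal tandem tracts with enough whole copies."""
    found = set()
    n = len(seq)
    for u in range(1, unit_max + 1):
        i = 0
        while i + u <= n:
            if seq[i] not in "ACGT":
                i += 1
                continue
            # maximal only: the previous position must break the period
            if i >= 1 and i + u - 1 < n and seq[i - 1] == seq[i - 1 + u]:
                if seq[i - 1] in "ACGT":
                    i += 1
                    continue
            j = i
            while j + u < n and seq[j + u] == seq[j] and seq[j + u] in "ACGT":
                j += 1
            span = j + u - i
            if span > u and span // u >= min_copies:
                ok = all(c in "ACGT" for c in seq[i : i + span])
                if ok:
                    found.add((i, i + span))
            i += 1
    return sorted(found)
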