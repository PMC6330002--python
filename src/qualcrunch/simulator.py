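"""Synthetic aligned-read generator with a known truth table.

Produces coordinate-sorted reads over a random diploid reference window,
with SNPs/indels at configurable density, Phred-calibrated base errors,
and optional planted anomalies (a novel insertion producing concordant
soft clips, a collapsed repeat doubling depth, a low-MAPQ tract, STR
tracts).  Everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .pileup import FLAG_REVERSE, ReadRecord

_BASES = "ACGT"


@dataclass(frozen=True)
class Variant:
    pos: int
    kind: str  # SNP | ins | del
    ref: str
    alt: str
    zygosity: str  # het | hom
    hap: int  # haplotype carrying a het variant (0/1); -1 for hom


@dataclass
class SimTruth:
    reference: str
    variants: List[Variant]
    str_tracts: List[Tuple[int, int, str]]  # (start, end, unit)
    anomalies: Dict[str, tuple]
    seed: int

    def to_table(self) -> List[Dict[str, object]]:
        """Minimal VCF-like rows for test assertions."""
        return [
            {
                "pos": v.pos,
                "kind": v.kind,
                "ref": v.ref,
                "alt": v.alt,
                "zygosity": v.zygosity,
            }
            for v in sorted(self.variants, key=lambda v: v.pos)
        ]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pos\tkind\tref\talt\tzygosity\n")
            for row in self.to_table():
                fh.write(
                    f"{row['pos']}\t{row['kind']}\t{row['ref']}\t"
                    f"{row['alt']}\t{row['zygosity']}\n"
                )


def _random_reference(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n).astype(np.uint8)


def _plant_strs(
    ref: np.ndarray, tracts: Sequence[Tuple[int, str, int]]
) -> List[Tuple[int, int, str]]:
    """Overwrite the reference with (pos, unit, copies) repeats."""
    placed = []
    for pos, unit, copies in tracts:
        codes = np.array([_BASES.index(b) for b in unit], dtype=np.uint8)
        rep = np.tile(codes, copies)
        ref[pos : pos + len(rep)] = rep
        placed.append((pos, pos + len(rep), unit))
    return placed


def _draw_variants(
    rng: np.random.Generator,
    ref: np.ndarray,
    var_density: float,
    het_fraction: float,
    read_len: int,
) -> List[Variant]:
    n = len(ref)
    count = int(round(var_density * n))
    if count == 0:
        return []
    # keep variants clear of the window edges and of each other
    lo, hi = read_len, max(read_len + 1, n - read_len)
    candidates = rng.permutation(np.arange(lo, hi))
    chosen: List[int] = []
    for p in candidates:
        if len(chosen) >= count:
            break
        if all(abs(p - c) > 12 for c in chosen):
            chosen.append(int(p))
    variants = []
    for p in sorted(chosen):
        r = rng.random()
        zyg = "het" if rng.random() < het_fraction else "hom"
        hap = int(rng.integers(0, 2)) if zyg == "het" else -1
        refb = _BASES[ref[p]]
        if r < 0.8:  # SNP
            alt = _BASES[(ref[p] + 1 + rng.integers(0, 3)) % 4]
            variants.append(Variant(p, "SNP", refb, alt, zyg, hap))
        elif r < 0.9:  # insertion after p
            ln = int(rng.integers(1, 4))
            ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=ln))
            variants.append(Variant(p, "ins", refb, refb + ins, zyg, hap))
        else:  # deletion of [p+1, p+1+ln)
            ln = int(rng.integers(1, 4))
            dele = "".join(_BASES[ref[p + 1 + k]] for k in range(ln))
            variants.append(Variant(p, "del", refb + dele, refb, zyg, hap))
    return variants


class _Haplotype:
    """Reference + applied variants, supporting CIGAR-aware read extraction."""

    def __init__(self, ref: np.ndarray, variants: Sequence[Variant], hap: int):
        self.n = len(ref)
        snp_seq = ref.copy()
        self.del_pos: set = set()
        self.ins: Dict[int, str] = {}
        altered: List[int] = []
        for v in variants:
            if v.zygosity == "het" and v.hap != hap:
                continue
            if v.kind == "SNP":
                snp_seq[v.pos] = _BASES.index(v.alt)
            elif v.kind == "ins":
                self.ins[v.pos] = v.alt[1:]
                altered.append(v.pos)
            else:  # del
                for k in range(len(v.ref) - 1):
                    self.del_pos.add(v.pos + 1 + k)
                altered.append(v.pos)
                altered.append(v.pos + len(v.ref))
        self.seq = "".join(_BASES[b] for b in snp_seq)
        self.altered = np.zeros(self.n + 1, dtype=bool)
        for p in altered:
            lo = max(0, p - 1)
            self.altered[lo : p + 2] = True

    def extract(self, start: int, read_len: int) -> Tuple[str, List[Tuple[str, int]], int]:
        """(seq, cigar, pos) for a read of ``read_len`` query bases at ``start``."""
        window = self.altered[start : min(self.n, start + read_len + 8)]
        if not window.any():
            end = min(self.n, start + read_len)
            return self.seq[start:end], [("M", end - start)], start
        parts: List[str] = []
        cig: List[Tuple[str, int]] = []
        n_q = 0
        rpos = start
        pos = None

        def push(op: str, ln: int) -> None:
            if cig and cig[-1][0] == op:
                cig[-1] = (op, cig[-1][1] + ln)
            else:
                cig.append((op, ln))

        while n_q < read_len and rpos < self.n:
            if rpos in self.del_pos:
                if n_q > 0:
                    push("D", 1)
            else:
                if pos is None:
                    pos = rpos
                parts.append(self.seq[rpos])
                push("M", 1)
                n_q += 1
            ins = self.ins.get(rpos)
            if ins and 0 < n_q < read_len:
                k = min(len(ins), read_len - n_q)
                parts.append(ins[:k])
                push("I", k)
                n_q += k
            rpos += 1
        while cig and cig[-1][0] == "D":
            cig.pop()
        return "".join(parts), cig, pos if pos is not None else start


def _draw_quals(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    q = np.rint(rng.normal(mean, sd, size=n)) if sd > 0 else np.full(n, round(mean))
    return np.clip(q, 2, 41).astype(np.int16)


def _inject_errors(
    rng: np.random.Generator, seq: str, qual: np.ndarray
) -> str:
    p = np.power(10.0, -qual.astype(np.float64) / 10.0)
    hit = np.flatnonzero(rng.random(len(qual)) < p)
    if not len(hit):
        return seq
    chars = list(seq)
    for i in hit:
        orig = chars[i]
        if orig in _BASES:
            others = _BASES.replace(orig, "")
            chars[i] = others[rng.integers(0, 3)]
    return "".join(chars)


def simulate(
    ref_len: int = 10_000,
    depth: float = 30.0,
    read_len: int = 100,
    err_rate: Optional[float] = None,
    var_density: float = 0.001,
    het_fraction: float = 0.5,
    anomalies: Optional[Dict[str, tuple]] = None,
    seed: int = 0,
    qual_mean: float = 37.0,
    qual_sd: float = 3.0,
    mapq: int = 60,
) -> Tuple[List[ReadRecord], SimTruth]:
    """Simulate ``round(depth * ref_len / read_len)`` coordinate-sorted reads.

    ``err_rate=None`` draws qualities from the configured normal and makes
    each base wrong with exactly its Phred-implied probability;
    ``err_rate=r`` instead assigns the constant quality ``round(-10*log10 r)``
    so the realised error rate is Phred-consistent and equals ``r``;
    ``err_rate=0`` disables errors entirely.

    ``anomalies`` keys: ``insertion=(pos, length)``, ``collapsed_repeat=
    (start, end)``, ``low_mapq=(start, end[, fraction])``, ``str=[(pos,
    unit, copies), ...]``.
    """
    if read_len > ref_len:
        raise ValueError("read_len must not exceed ref_len")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if err_rate is not None and not 0 <= err_rate < 1:
        raise ValueError("err_rate must lie in [0, 1)")
    anomalies = dict(anomalies or {})
    rng = np.random.default_rng(seed)

    ref = _random_reference(rng, ref_len)
    str_tracts = _plant_strs(ref, anomalies.get("str", []))
    variants = _draw_variants(rng, ref, var_density, het_fraction, read_len)
    haps = [_Haplotype(ref, variants, h) for h in (0, 1)]

    if err_rate is not None and err_rate > 0:
        qual_mean = -10.0 * math.log10(err_rate)
        qual_sd = 0.0

    n_reads = int(round(depth * ref_len / read_len))
    starts = list(rng.integers(0, ref_len - read_len + 1, size=n_reads))
    if "collapsed_repeat" in anomalies:
        cs, ce = anomalies["collapsed_repeat"][:2]
        n_extra = int(round(depth * (ce - cs) / read_len))
        lo = max(0, cs - read_len + 1)
        starts += list(rng.integers(lo, min(ce, ref_len - read_len) + 1, size=n_extra))

    ins_anom = anomalies.get("insertion")
    low_anom = anomalies.get("low_mapq")

    records: List[ReadRecord] = []
    for s in starts:
        hap = int(rng.integers(0, 2))
        seq, cigar, pos = haps[hap].extract(int(s), read_len)
        if not seq:
            continue
        qual = _draw_quals(rng, len(seq), qual_mean, qual_sd)
        if err_rate != 0:
            seq = _inject_errors(rng, seq, qual)
        flags = FLAG_REVERSE if rng.random() < 0.5 else 0
        rec = ReadRecord(
            name="", ref_id=0, pos=pos, cigar=cigar, seq=seq, qual=qual,
            mapq=mapq, flags=flags,
        )
        if ins_anom is not None:
            rec = _apply_insertion_clip(rec, int(ins_anom[0]))
            if rec is None:
                continue
        if low_anom is not None:
            ls, le = int(low_anom[0]), int(low_anom[1])
            frac = float(low_anom[2]) if len(low_anom) > 2 else 1.0
            if rec.pos < le and rec.ref_end > ls and rng.random() < frac:
                rec.mapq = 0
        records.append(rec)

    records.sort(key=lambda r: r.pos)
    for i, r in enumerate(records):
        r.name = f"sim{i:07d}"
    truth = SimTruth(
        reference="".join(_BASES[b] for b in ref),
        variants=variants,
        str_tracts=str_tracts,
        anomalies=anomalies,
        seed=seed,
    )
    return records, truth


def _apply_insertion_clip(rec: ReadRecord, bp: int) -> Optional[ReadRecord]:
    """Soft-clip a read at a novel-insertion breakpoint it straddles."""
    if not (rec.pos < bp < rec.ref_end):
        return rec
    # only simple alignments are clipped; indel-bearing reads stay put
    if len(rec.cigar) != 1 or rec.cigar[0][0] != "M":
        return rec
    mid = (rec.pos + rec.ref_end) // 2
    off = bp - rec.pos
    if mid < bp:  # keep the left part aligned, clip the right
        rec.cigar = [("M", off), ("S", len(rec.seq) - off)]
    else:  # clip the left part, alignment restarts at the breakpoint
        rec.cigar = [("S", off), ("M", len(rec.seq) - off)]
        rec.pos = bp
    return rec


def to_sam(
    records: Sequence[ReadRecord],
    path,
    ref_name: str = "sim1",
    ref_len: Optional[int] = None,
) -> None:
    """Write simulated records as a coordinate-sorted SAM file."""
    import pysam

    if ref_len is None:
        ref_len = max((r.ref_end for r in records), default=0) + 1
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref_name, "LN": int(ref_len)}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.reference_id = 0
            a.reference_start = r.pos
            a.mapping_quality = r.mapq
            a.flag = r.flags
            a.cigarstring = "".join(f"{ln}{op}" for op, ln in r.cigar)
            a.query_sequence = r.seq
            a.query_qualities = [int(q) for q in r.qual]
            for tag, val in r.aux:
                a.set_tag(tag, val)
            out.write(a)
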