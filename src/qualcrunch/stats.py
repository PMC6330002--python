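"""Quality-stream measurements: entropy, distinct symbols, gzip proxy."""

from __future__ import annotations

import zlib
from typing import Tuple

import numpy as np
import pysam


def quality_stream(path) -> np.ndarray:
    """Concatenated per-base qualities of every record carrying them."""
    chunks = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            q = rec.query_qualities
            if q is not None:
                chunks.append(np.asarray(q, dtype=np.uint8))
    if not chunks:
        return np.zeros(0, dtype=np.uint8)
    return np.concatenate(chunks)


def symbol_counts(quals: np.ndarray) -> np.ndarray:
    return np.bincount(np.asarray(quals, dtype=np.int64), minlength=94)


def shannon_entropy(counts: np.ndarray) -> float:
    """Order-0 entropy in bits per symbol."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def distinct_symbols(counts: np.ndarray) -> int:
    return int((counts > 0).sum())


def gzip_size(quals: np.ndarray, level: int = 6) -> int:
    """zlib-compressed byte size of the quality stream (a size proxy)."""
    return len(zlib.compress(np.asarray(quals, dtype=np.uint8).tobytes(), level))


def summarize(path) -> dict:
    q = quality_stream(path)
    counts = symbol_counts(q)
    return {
        "bases": int(q.size),
        "distinct_symbols": distinct_symbols(counts),
        "entropy_bits": shannon_entropy(counts),
        "gzip_bytes": gzip_size(q),
    }
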