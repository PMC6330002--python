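"""Preset bundles mapping a 1..9 compression level onto concrete knobs.

Level 1 is conservative: every detector on with loose thresholds, wide
padding, disagreeing qualities kept verbatim, no P-block.  Level 9 is
aggressive: tight thresholds, narrow padding, disagreeing qualities
quantized.  Intermediate levels interpolate.  ``tuned()`` mirrors the
spirit of a hand-optimised aggressive profile (confidence bar 60, MAPQ
cutoff 30, depth ceiling 100, P-block 8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .consensus import CallerParams
from .heuristics import HeuristicParams
from .rewrite import QualityPolicy


@dataclass(frozen=True)
class Bundle:
    policy: QualityPolicy
    heuristics: HeuristicParams
    caller: CallerParams


def _lerp(a: float, b: float, t: float) -> float:
    return a + (b - a) * t


def preset(level: int = 1, pblock_p: int = 0) -> Bundle:
    """Bundle for a compression level in 1..9 (higher = more aggressive)."""
    if not 1 <= level <= 9:
        raise ValueError("preset level must be in 1..9")
    t = (level - 1) / 8.0
    if level <= 3:
        disagree = "keep"
    elif level <= 8:
        disagree = "low"
    else:
        disagree = "quantize"
    policy = QualityPolicy(
        qual_high=40,
        qual_low=10,
        disagree_mode=disagree,
        pblock_p=pblock_p,
        preset_level=level,
    )
    heur = HeuristicParams(
        clip_min_count=int(round(_lerp(3, 8, t))),
        clip_min_fraction=_lerp(0.1, 0.4, t),
        depth_max=int(round(_lerp(150, 500, t))),
        mapq_low=int(round(_lerp(20, 5, t))),
        low_mapq_fraction=_lerp(0.25, 0.6, t),
        keep_colocated_high_mapq=level <= 4,
        max_alleles=2,
        str_unit_max=4,
        str_min_copies=int(round(_lerp(4, 6, t))),
        pad=int(round(_lerp(20, 8, t))),
    )
    caller = CallerParams(conf_threshold=round(_lerp(60, 30, t)))
    return Bundle(policy=policy, heuristics=heur, caller=caller)


def tuned() -> Bundle:
    """Aggressive profile with hand-tuned retention thresholds."""
    b = preset(9, pblock_p=8)
    return Bundle(
        policy=b.policy,
        heuristics=replace(b.heuristics, mapq_low=30, depth_max=100),
        caller=replace(b.caller, conf_threshold=60),
    )


def full_retention() -> Bundle:
    """Degenerate lossless mode: every covered locus is retained verbatim.

    An infinite confidence bar makes the always-on low-confidence detector
    mask every covered base; disagree mode 'keep' and P-block off preserve
    the rest (soft clips, insertions) untouched.
    """
    policy = QualityPolicy(disagree_mode="keep", pblock_p=0, preset_level=1)
    heur = HeuristicParams(enabled=(), pad=0)
    caller = CallerParams(conf_threshold=math.inf)
    return Bundle(policy=policy, heuristics=heur, caller=caller)
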