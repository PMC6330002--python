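import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qualcrunch.consensus import CallerParams, call_entries
from qualcrunch.heuristics import (
    HeuristicParams,
    RetentionMask,
    assemble_mask,
    detect_excess_alleles,
    detect_excess_depth,
    detect_low_conf_calls,
    detect_low_mapq,
    detect_softclip_concordance,
    detect_str,
    find_tandem_tracts,
    merge_intervals,
)
from qualcrunch.pileup import build_pileup, expand_reads, softclip_positions
from qualcrunch.simulator import simulate

from .conftest import mk_read
from .oracles import oracle_merge, oracle_tandem


def entries_for(reads, span):
    return expand_reads(reads, span)


class TestSoftclipConcordance:
    def test_no_clips(self):
        reads = [mk_read(100 + i, "50M", name=f"r{i}") for i in range(10)]
        ent = entries_for(reads, (100, 200))
        assert detect_softclip_concordance([], ent, HeuristicParams()) == []

    def test_concordant_site_fires_with_padding(self):
        # 5 clipped reads at site 150 over ~10x spanning depth
        reads = sorted(
            [mk_read(100 + i * 2, "50M", name=f"m{i}") for i in range(10)]
            + [mk_read(110, "40M10S", name=f"c{i}") for i in range(5)],
            key=lambda r: r.pos,
        )
        clips = [c for r in reads for c in softclip_positions(r)]
        ent = entries_for(reads, (90, 220))
        params = HeuristicParams(clip_min_count=3, clip_min_fraction=0.3, pad=10)
        ivs = detect_softclip_concordance(clips, ent, params)
        assert ivs == [(140, 160)]

    def test_below_count_threshold_silent(self):
        reads = sorted(
            [mk_read(100 + i * 2, "50M", name=f"m{i}") for i in range(10)]
            + [mk_read(110, "40M10S", name="c0")],
            key=lambda r: r.pos,
        )
        clips = [c for r in reads for c in softclip_positions(r)]
        ent = entries_for(reads, (90, 220))
        params = HeuristicParams(clip_min_count=3, clip_min_fraction=0.1, pad=10)
        assert detect_softclip_concordance(clips, ent, params) == []

    def test_simulated_insertion_breakpoint_covered(self):
        reads, truth = simulate(ref_len=4000, depth=30, read_len=100, seed=11,
                                var_density=0.0,
                                anomalies={"insertion": (2000, 40)})
        ent = entries_for(reads, (0, 4000))
        clips = [c for r in reads if r.eligible for c in softclip_positions(r)]
        params = HeuristicParams(clip_min_count=3, clip_min_fraction=0.3, pad=10)
        ivs = detect_softclip_concordance(clips, ent, params)
        assert any(s <= 2000 < e for s, e in ivs), ivs


class TestExcessDepth:
    def test_uniform_depth_silent(self):
        reads, _ = simulate(ref_len=1000, depth=30, read_len=100, seed=2,
                            var_density=0.0)
        ent = entries_for(reads, (0, 1000))
        assert detect_excess_depth(ent, HeuristicParams(depth_max=100)) == []

    def test_deep_stripe_flagged_exactly(self):
        reads = sorted(
            [mk_read(200, "50M", name=f"d{i}") for i in range(150)],
            key=lambda r: r.pos,
        )
        ent = entries_for(reads, (0, 400))
        params = HeuristicParams(depth_max=100, pad=0)
        assert detect_excess_depth(ent, params) == [(200, 250)]

    def test_collapsed_repeat_flagged(self):
        reads, _ = simulate(ref_len=4000, depth=30, read_len=100, seed=13,
                            var_density=0.0,
                            anomalies={"collapsed_repeat": (2000, 2400)})
        ent = entries_for(reads, (0, 4000))
        ivs = detect_excess_depth(ent, HeuristicParams(depth_max=45, pad=0))
        assert ivs, "doubled-depth tract not flagged"
        assert any(s < 2400 and e > 2000 for s, e in ivs)


class TestLowMapq:
    def test_all_high_mapq_silent(self):
        reads = [mk_read(10 + i, "30M", name=f"r{i}", mapq=60) for i in range(5)]
        ent = entries_for(reads, (0, 100))
        ivs, whole = detect_low_mapq(ent, reads, HeuristicParams(mapq_low=10))
        assert ivs == [] and whole == set()

    def test_single_low_mapq_read_whole_retained(self):
        reads = [mk_read(10, "30M", name="lo", mapq=5),
                 mk_read(12, "30M", name="hi", mapq=60)]
        ent = entries_for(reads, (0, 100))
        ivs, whole = detect_low_mapq(ent, reads, HeuristicParams(mapq_low=10))
        assert {r.name for r in whole} == {"lo"}

    def test_dense_low_mapq_interval_and_colocated(self):
        reads, _ = simulate(ref_len=4000, depth=30, read_len=100, seed=17,
                            var_density=0.0,
                            anomalies={"low_mapq": (2000, 2500, 0.4)})
        ent = entries_for(reads, (0, 4000))
        params = HeuristicParams(mapq_low=10, low_mapq_fraction=0.25,
                                 keep_colocated_high_mapq=True, pad=10)
        ivs, whole = detect_low_mapq(ent, reads, params)
        assert any(s < 2500 and e > 2000 for s, e in ivs), ivs
        high_colocated = [r for r in whole if r.mapq >= 10]
        assert high_colocated, "colocated high-MAPQ reads not retained"
        for r in high_colocated:
            assert any(r.pos < e and r.ref_end > s for s, e in ivs)

    def test_mask_monotone_as_threshold_loosens(self):
        reads, _ = simulate(ref_len=2000, depth=25, read_len=100, seed=19,
                            var_density=0.0,
                            anomalies={"low_mapq": (800, 1200, 0.5)})
        ent = entries_for(reads, (0, 2000))
        strict, _ = detect_low_mapq(
            ent, reads, HeuristicParams(mapq_low=10, low_mapq_fraction=0.6))
        loose, _ = detect_low_mapq(
            ent, reads, HeuristicParams(mapq_low=10, low_mapq_fraction=0.3))
        strict_bases = {p for s, e in strict for p in range(s, e)}
        loose_bases = {p for s, e in loose for p in range(s, e)}
        assert strict_bases <= loose_bases


class TestExcessAlleles:
    def _col_entries(self, composition):
        reads = []
        pos = 0
        for i, (base, count) in enumerate(composition):
            for j in range(count):
                reads.append(mk_read(100, "1M", base, [30], name=f"{base}{j}"))
        return entries_for(reads, (100, 101))

    def test_single_allele_silent(self):
        ent = self._col_entries([("A", 10)])
        assert detect_excess_alleles(ent, HeuristicParams(pad=0)) == []

    def test_two_alleles_silent(self):
        ent = self._col_entries([("A", 5), ("C", 4)])
        assert detect_excess_alleles(ent, HeuristicParams(pad=0)) == []

    def test_three_supported_alleles_fire(self):
        ent = self._col_entries([("A", 5), ("C", 4), ("G", 3)])
        assert detect_excess_alleles(ent, HeuristicParams(pad=0)) == [(100, 101)]

    def test_singleton_errors_do_not_fire(self):
        ent = self._col_entries([("A", 20), ("C", 20), ("G", 1), ("T", 1)])
        assert detect_excess_alleles(ent, HeuristicParams(pad=0)) == []

    def test_low_support_fraction_does_not_fire(self):
        # 2 G reads but < 10% of depth 40
        ent = self._col_entries([("A", 19), ("C", 19), ("G", 2)])
        assert detect_excess_alleles(ent, HeuristicParams(pad=0)) == []


class TestLowConfCalls:
    def test_confident_everywhere_silent(self):
        reads = [mk_read(i, "100M", name=f"r{i}") for i in range(0, 50)]
        ent = entries_for(reads, (40, 60))  # deep interior only
        calls = call_entries(ent, CallerParams(conf_threshold=30))
        assert detect_low_conf_calls(calls, CallerParams(conf_threshold=30), 5) == []

    def test_single_low_locus_padded(self):
        reads = [mk_read(100, "1M", "A", [20], name="solo")]
        ent = entries_for(reads, (100, 101))
        calls = call_entries(ent, CallerParams(conf_threshold=30))
        ivs = detect_low_conf_calls(calls, CallerParams(conf_threshold=30), 5)
        assert ivs == [(95, 106)]

    def test_low_coverage_het_site_retained(self):
        reads, truth = simulate(ref_len=3000, depth=4, read_len=100, seed=19,
                                var_density=0.003, het_fraction=1.0)
        het_snps = [v for v in truth.variants if v.kind == "SNP"]
        assert het_snps
        ent = entries_for(reads, (0, 3000))
        cp = CallerParams(conf_threshold=30)
        calls = call_entries(ent, cp)
        ivs = detect_low_conf_calls(calls, cp, 10)
        for v in het_snps:
            assert any(s <= v.pos < e for s, e in ivs), f"het at {v.pos} missed"


class TestStrDetection:
    def test_partial_copies_do_not_qualify(self):
        assert find_tandem_tracts("ACGTACGTA", 4, 3) == []

    def test_homopolymer_tract(self):
        seq = "GC" + "A" * 6 + "GC"
        assert find_tandem_tracts(seq, 4, 3) == [(2, 8)]
        params = HeuristicParams(str_unit_max=4, str_min_copies=3, pad=0)
        assert detect_str(seq, 0, params) == [(2, 8)]

    def test_planted_dinucleotide_found_exactly(self):
        rng = np.random.default_rng(23)
        while True:
            seq = "".join(rng.choice(list("ACGT"), size=200))
            if not oracle_tandem(seq, 4, 5):
                break
        planted = seq[:90] + "AC" * 8 + seq[106:]
        tracts = find_tandem_tracts(planted, 4, 5)
        oracle = oracle_tandem(planted, 4, 5)
        assert tracts == oracle
        assert any(s <= 90 and e >= 106 for s, e in tracts)

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet="ACGTN*", min_size=0, max_size=80),
           st.integers(1, 4), st.integers(2, 5))
    def test_matches_quadratic_oracle(self, seq, unit_max, min_copies):
        assert find_tandem_tracts(seq, unit_max, min_copies) == oracle_tandem(
            seq, unit_max, min_copies
        )

    def test_indel_span_extension(self):
        seq = "GC" + "A" * 8 + "GC"
        params = HeuristicParams(str_unit_max=4, str_min_copies=3, pad=0)
        ivs = detect_str(seq, 0, params, indel_spans=[(8, 14)])
        assert ivs == [(2, 14)]


class TestAssembleMask:
    def test_empty(self):
        mask = assemble_mask({})
        assert mask.intervals == [] and mask.whole_reads == set()

    def test_merge_with_tag_union(self):
        mask = assemble_mask({"softclip": [(10, 20)], "str": [(15, 30)]})
        assert mask.intervals == [(10, 30, frozenset({"softclip", "str"}))]

    def test_adjacent_intervals_merge(self):
        mask = assemble_mask({"depth": [(10, 20), (20, 25)]})
        assert mask.plain_intervals == [(10, 25)]

    def test_order_independent_and_idempotent(self):
        a = assemble_mask({"depth": [(5, 9)], "str": [(1, 6)], "mapq": [(20, 30)]})
        b = assemble_mask({"mapq": [(20, 30)], "depth": [(5, 9)], "str": [(1, 6)]})
        assert a.intervals == b.intervals
        again = assemble_mask(
            {t: [(s, e)] for s, e, ts in a.intervals for t in ts}
        )
        assert again.plain_intervals == a.plain_intervals

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 95), st.integers(1, 20),
                              st.sampled_from(["softclip", "depth", "str"])),
                    max_size=15))
    def test_matches_paint_oracle(self, triples):
        tagged = [(s, s + ln, tag) for s, ln, tag in triples]
        by_reason = {}
        for s, e, tag in tagged:
            by_reason.setdefault(tag, []).append((s, e))
        mask = assemble_mask(by_reason)
        assert mask.intervals == oracle_merge(tagged, 130)

    def test_cover_queries(self):
        mask = assemble_mask({"depth": [(10, 20), (40, 45)]})
        assert mask.covers(10) and mask.covers(19) and not mask.covers(20)
        pos = np.array([5, 10, 19, 20, 40, 44, 45])
        got = mask.cover_positions(pos)
        assert got.tolist() == [False, True, True, False, True, True, False]


class TestDegenerateFullRetention:
    def test_infinite_threshold_masks_every_covered_locus(self):
        reads, _ = simulate(ref_len=1000, depth=10, read_len=50, seed=29,
                            var_density=0.0)
        ent = entries_for(reads, (0, 1000))
        cp = CallerParams(conf_threshold=np.inf)
        calls = call_entries(ent, cp)
        ivs = detect_low_conf_calls(calls, cp, 0)
        mask = assemble_mask({"lowconf": ivs})
        depth = ent.depth_profile()
        covered = np.flatnonzero(depth > 0)
        assert mask.cover_positions(covered).all()


def test_merge_intervals_basic():
    assert merge_intervals([(5, 10), (9, 12), (20, 21), (-5, 2)]) == [
        (0, 2), (5, 12), (20, 21)
    ]
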