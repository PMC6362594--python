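"""SV-to-segment breakpoint matching and the class comparison statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from crispy import sv_overlap as svo
from crispy.io_formats import CopyNumberSegment, SvRecord, SvType
from crispy.simulate import SimulationConfig, simulate_genome


def sv(sv_type, pos1, pos2, score=90.0, chrom="chr1"):
    return SvRecord(sv_type, chrom, pos1, chrom, pos2, score)


def seg(start, end, copies=2.0, chrom="chr1"):
    return CopyNumberSegment(chrom, start, end, copies)


class TestConfidentFilter:
    def test_scored_tandem_duplication_kept(self):
        assert svo.filter_confident_svs([sv(SvType.TANDEM_DUPLICATION, 1, 2)]) != []

    def test_missing_assembly_score_dropped(self):
        assert svo.filter_confident_svs(
            [sv(SvType.TANDEM_DUPLICATION, 1, 2, score=None)]
        ) == []

    def test_scored_inversion_dropped_by_type(self):
        assert svo.filter_confident_svs([sv(SvType.INVERSION, 1, 2)]) == []


class TestMatching:
    def test_breakpoints_within_tolerance_match_with_offsets(self):
        segments = {"chr1": [seg(1000, 50000)]}
        (m,) = svo.match_sv_to_segments(
            [sv(SvType.TANDEM_DUPLICATION, 995, 50120)], segments
        )
        assert (m.start_offset, m.end_offset) == (-5, 120)

    def test_one_breakpoint_out_of_tolerance_fails(self):
        segments = {"chr1": [seg(1000, 50000)]}
        assert svo.match_sv_to_segments(
            [sv(SvType.TANDEM_DUPLICATION, 995, 70000)], segments
        ) == []

    @pytest.mark.parametrize("offset,matches", [(10_000, True), (10_001, False)])
    def test_tolerance_boundary_inclusive(self, offset, matches):
        segments = {"chr1": [seg(100_000, 200_000)]}
        records = svo.match_sv_to_segments(
            [sv(SvType.DELETION, 100_000 + offset, 200_000)], segments
        )
        assert bool(records) is matches

    def test_equals_brute_force_all_pairs(self):
        rng = np.random.default_rng(4)
        segments = {}
        svs = []
        for chrom in ("chr1", "chr2"):
            bounds = np.sort(rng.choice(np.arange(1, 50), 6, replace=False)) * 10_000
            segments[chrom] = [
                CopyNumberSegment(chrom, int(a), int(b), 2.0)
                for a, b in zip(bounds, bounds[1:])
            ]
            for _ in range(15):
                p1 = int(rng.integers(0, 480_000))
                p2 = p1 + int(rng.integers(1, 200_000))
                svs.append(SvRecord(SvType.TANDEM_DUPLICATION, chrom, p1, chrom, p2, 80.0))
        got = {
            (id(m.sv), m.segment.chrom, m.segment.start)
            for m in svo.match_sv_to_segments(svs, segments, 10_000)
        }
        expected = set()
        for s in svs:
            for chrom, lst in segments.items():
                for g in lst:
                    if (s.chrom1 == chrom and abs(s.pos1 - g.start) <= 10_000
                            and abs(s.pos2 - g.end) <= 10_000):
                        expected.add((id(s), chrom, g.start))
        assert got == expected

    def test_match_count_monotone_in_tolerance(self):
        rng = np.random.default_rng(8)
        segments = {"chr1": [seg(i * 100_000, (i + 1) * 100_000) for i in range(10)]}
        svs = [
            sv(SvType.DELETION, int(rng.integers(0, 900_000)),
               int(rng.integers(900_001, 1_100_000)))
            for _ in range(30)
        ]
        counts = [
            len(svo.match_sv_to_segments(svs, segments, tol))
            for tol in (50_000, 20_000, 10_000, 1_000, 0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestClassComparison:
    def _matches(self, dup_segs, del_segs):
        out = []
        for s in dup_segs:
            out.append(svo.SvSegmentMatch(
                sv(SvType.TANDEM_DUPLICATION, s.start, s.end), s, 0, 0))
        for s in del_segs:
            out.append(svo.SvSegmentMatch(
                sv(SvType.DELETION, s.start, s.end), s, 0, 0))
        return out

    def test_identical_values_give_t0_p1(self):
        dup = [seg(i * 10, i * 10 + 5) for i in range(3)]
        dele = [seg(1000 + i * 10, 1005 + i * 10) for i in range(3)]
        ratios = {f"chr1:{s.start}-{s.end}": 1.0 for s in dup + dele}
        res = svo.sv_class_comparison(self._matches(dup, dele), ratios)
        assert res["tests"]["ratio"] == {"t": 0.0, "p": 1.0, "degenerate": True}

    def test_zero_variance_distinct_means_flagged_degenerate(self):
        dup = [seg(i * 10, i * 10 + 5) for i in range(3)]
        dele = [seg(1000 + i * 10, 1005 + i * 10) for i in range(3)]
        ratios = {f"chr1:{s.start}-{s.end}": 2.0 for s in dup}
        ratios.update({f"chr1:{s.start}-{s.end}": 0.5 for s in dele})
        res = svo.sv_class_comparison(self._matches(dup, dele), ratios)
        assert res["tests"]["ratio"]["degenerate"] is True
        assert res["tests"]["ratio"]["p"] == 0.0

    def test_welch_t_matches_closed_form(self):
        a = np.array([2.1, 1.8, 2.5, 2.2, 1.9])
        b = np.array([0.7, 0.9, 0.6, 0.8, 0.5])
        dup = [seg(i * 10, i * 10 + 5) for i in range(5)]
        dele = [seg(1000 + i * 10, 1005 + i * 10) for i in range(5)]
        ratios = {f"chr1:{s.start}-{s.end}": v for s, v in zip(dup, a)}
        ratios.update({f"chr1:{s.start}-{s.end}": v for s, v in zip(dele, b)})
        res = svo.sv_class_comparison(self._matches(dup, dele), ratios)
        # closed-form Welch statistic and Welch-Satterthwaite df
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 4 + vb ** 2 / 4)
        assert res["tests"]["ratio"]["t"] == pytest.approx(t)
        assert res["tests"]["ratio"]["p"] == pytest.approx(2 * sps.t.sf(abs(t), df))
        assert res["classes"]["tandem_duplication"]["median_ratio"] == np.median(a)

    def test_single_member_class_statistics_omitted(self):
        dup = [seg(0, 5)]
        dele = [seg(1000, 1005), seg(1010, 1015)]
        ratios = {f"chr1:{s.start}-{s.end}": 1.0 for s in dup + dele}
        res = svo.sv_class_comparison(self._matches(dup, dele), ratios)
        assert "ratio" not in res["tests"]


class TestFixtureRecovery:
    def test_generated_focal_events_recovered_and_ratios_separate(self):
        cfg = SimulationConfig(seed=3)
        genome = simulate_genome(cfg)
        confident = svo.filter_confident_svs(genome.svs)
        n_focal_events = sum(len(m) for m in cfg.focal_multipliers)
        assert len(confident) == n_focal_events  # decoys removed
        matches = svo.match_sv_to_segments(confident, genome.segments)
        matched_svs = {id(m.sv) for m in matches}
        assert len(matched_svs) / n_focal_events >= 0.95

        all_segs = [s for lst in genome.segments.values() for s in lst]
        from crispy import copy_number as cn
        chrom_cn = {c: cn.chromosome_cn(all_segs, c) for c in genome.segments}
        ratios = {
            f"{s.chrom}:{s.start}-{s.end}": s.copy_number / chrom_cn[s.chrom]
            for s in all_segs
        }
        res = svo.sv_class_comparison(matches, ratios)
        assert res["classes"]["tandem_duplication"]["median_ratio"] > 1
        assert res["classes"]["deletion"]["median_ratio"] < 1
        assert res["tests"]["ratio"]["p"] < 0.05
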