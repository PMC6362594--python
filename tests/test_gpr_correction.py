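"""Segment assignment, GP fitting against linear-algebra oracles, and correction."""

import warnings

import numpy as np
import pandas as pd
import pytest

from crispy import gpr_correction as gpr
from crispy.io_formats import CopyNumberSegment, GuideRecord


def seg(chrom, start, end, copies):
    return CopyNumberSegment(chrom, start, end, copies)


def make_stats(x, y, n_guides=12):
    return [
        gpr.SegmentStat(seg("c", i * 100, i * 100 + 50, 2.0), f"c:{i*100}-{i*100+50}",
                        float(xi), float(yi), n_guides, n_guides >= 10)
        for i, (xi, yi) in enumerate(zip(x, y))
    ]


class TestAssignGuides:
    SEGMENTS = {"chr1": [seg("chr1", 0, 1000, 2), seg("chr1", 1000, 2000, 4)]}

    def test_guide_inside_segment(self):
        lib = [GuideRecord("sg1", "A", "chr1", 100, 120)]
        assert gpr.assign_guides_to_segments(lib, self.SEGMENTS)["sg1"].start == 0

    def test_midpoint_on_boundary_goes_right(self):
        # guide [990, 1010) has midpoint 1000, which half-open containment
        # places in the segment starting at 1000
        lib = [GuideRecord("sg1", "A", "chr1", 990, 1010)]
        assert gpr.assign_guides_to_segments(lib, self.SEGMENTS)["sg1"].start == 1000

    def test_chromosome_without_segments_unassigned(self):
        lib = [GuideRecord("sg1", "A", "chrX", 100, 120)]
        assert gpr.assign_guides_to_segments(lib, self.SEGMENTS) == {}


class TestSegmentStats:
    def _run(self, n_guides):
        segments = {"chr1": [seg("chr1", 0, 9000, 2), seg("chr1", 9000, 10000, 6)]}
        lib = [GuideRecord(f"sg{i}", "A", "chr1", 9000 + i * 10, 9020 + i * 10)
               for i in range(n_guides)]
        fc = pd.Series(np.linspace(-1, 0, n_guides), index=[g.guide_id for g in lib])
        mapping = gpr.assign_guides_to_segments(lib, segments)
        return gpr.segment_stats(fc, mapping, segments)

    @pytest.mark.parametrize("n,eligible", [(9, False), (10, True)])
    def test_min_guides_strictly_less_than_10(self, n, eligible):
        (stat,) = self._run(n)
        assert stat.n_guides == n and stat.eligible is eligible

    def test_ratio_uses_size_weighted_chromosome_cn(self):
        (stat,) = self._run(10)
        # chromosome CN = (2*9000 + 6*1000) / 10000 = 2.4
        assert stat.ratio == pytest.approx(6 / 2.4)
        assert stat.mean_fc == pytest.approx(-0.5)


class TestFitAndPredict:
    def test_constant_function_recovery(self):
        x = np.linspace(0.5, 4, 20)
        stats = make_stats(x, np.full(20, -1.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = gpr.fit_bias_model(
                stats,
                gpr.KernelConfig(sigma2_bounds=(1e-3, 1e5),
                                 psi_bounds=(1e-12, 10), seed=0),
            )
        pred, _ = gpr.predict_bias(model, x)
        assert np.abs(pred + 1.0).max() < 1e-6

    def test_piecewise_linear_curve_recovered_on_dense_x(self):
        x = np.linspace(0.5, 4, 50)
        y = -np.maximum(0.0, x - 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = gpr.fit_bias_model(
                make_stats(x, y),
                gpr.KernelConfig(psi_bounds=(1e-9, 10), seed=0),
            )
        grid = np.linspace(0.5, 4, 100)
        pred, _ = gpr.predict_bias(model, grid)
        assert np.abs(pred - (-np.maximum(0.0, grid - 1.0))).max() < 0.05

    def test_five_point_prediction_matches_kernel_matrix_solve(self):
        x = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
        y = np.array([0.0, -0.1, -0.9, -2.1, -3.0])
        model = gpr.fit_bias_model(make_stats(x, y), gpr.KernelConfig(seed=0))
        xs = np.array([0.7, 1.5, 2.5, 3.7, 5.0])
        # independent oracle: direct linear algebra with the fitted kernel
        def k_rbf(a, b):
            return model.sigma2 * np.exp(-((a[:, None] - b[None, :]) ** 2)
                                         / (2 * model.theta ** 2))
        K = k_rbf(x, x) + model.psi * np.eye(5) + 1e-10 * np.eye(5)
        expected = k_rbf(xs, x) @ np.linalg.solve(K, y)
        pred, _ = gpr.predict_bias(model, xs)
        np.testing.assert_allclose(pred, expected, rtol=1e-6, atol=1e-8)

    def test_far_from_training_reverts_to_prior(self):
        x = np.linspace(0.5, 4, 20)
        model = gpr.fit_bias_model(make_stats(x, -x + 1), gpr.KernelConfig(seed=0))
        mean, sd = gpr.predict_bias(model, [1e6])
        assert mean[0] == pytest.approx(0.0, abs=1e-9)
        assert sd[0] == pytest.approx(np.sqrt(model.sigma2 + model.psi), rel=1e-9)

    def test_duplicated_points_fit_succeeds_with_finite_predictions(self):
        x = np.repeat([1.0, 2.0, 3.0], 4)
        y = np.tile([-0.1, -1.0, -2.0], 4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = gpr.fit_bias_model(make_stats(x, y), gpr.KernelConfig(seed=0))
        pred, sd = gpr.predict_bias(model, np.linspace(0.5, 3.5, 7))
        assert np.isfinite(pred).all() and np.isfinite(sd).all() and (sd >= 0).all()

    def test_insufficient_segments_refused(self):
        with pytest.raises(ValueError, match="insufficient segments"):
            gpr.fit_bias_model(make_stats([1.0, 2.0], [0.0, -1.0]))
        with pytest.raises(ValueError, match="insufficient segments"):
            gpr.fit_bias_model(make_stats([1.0, 1.0, 1.0], [0.0, -0.1, 0.1]))

    def test_ineligible_segments_excluded_from_training(self):
        x = np.linspace(0.5, 4, 25)
        stats = make_stats(x, np.zeros(25))
        outlier = make_stats([2.0], [-50.0], n_guides=5)  # below min_guides
        model = gpr.fit_bias_model(stats + outlier, gpr.KernelConfig(seed=0))
        assert len(model.train_x) == 25
        pred, _ = gpr.predict_bias(model, [2.0])
        assert abs(pred[0]) < 0.1

    def test_refit_with_same_seed_is_bit_reproducible(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0.5, 4, 30)
        y = -np.maximum(0, x - 1) + rng.normal(0, 0.1, 30)
        cfg = gpr.KernelConfig(seed=11)
        m1 = gpr.fit_bias_model(make_stats(x, y), cfg)
        m2 = gpr.fit_bias_model(make_stats(x, y), cfg)
        assert (m1.sigma2, m1.theta, m1.psi) == (m2.sigma2, m2.theta, m2.psi)
        p1, s1 = gpr.predict_bias(m1, x)
        p2, s2 = gpr.predict_bias(m2, x)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(s1, s2)


class TestCorrectSample:
    def test_corrected_is_original_minus_bias_exactly(self, pipeline):
        gt = pipeline["result"].guide_table
        np.testing.assert_array_equal(
            gt["corrected_fc"].to_numpy(),
            gt["original_fc"].to_numpy() - gt["predicted_bias"].to_numpy(),
        )

    def test_guides_sharing_a_segment_share_the_bias(self, pipeline):
        gt = pipeline["result"].guide_table
        per_seg = gt[gt["assigned"]].groupby("segment_id")["predicted_bias"].nunique()
        assert (per_seg == 1).all()

    def test_small_segments_still_receive_predictions(self):
        # 30 eligible training segments plus one 4-guide segment: the filter
        # affects training only, the small segment's guides are still corrected
        segments = {"chr1": [seg("chr1", i * 1000, (i + 1) * 1000, 2 + (i % 5))
                             for i in range(30)],
                    "chr2": [seg("chr2", 0, 1000, 8), seg("chr2", 1000, 100000, 2)]}
        lib = []
        for i in range(30):
            lib += [GuideRecord(f"sg{i}_{j}", f"G{i}", "chr1", i * 1000 + 10 * j + 5,
                                i * 1000 + 10 * j + 25) for j in range(10)]
        lib += [GuideRecord(f"sgs{j}", "GS", "chr2", 10 * j + 5, 10 * j + 25)
                for j in range(4)]
        lib += [GuideRecord(f"sgb{j}", "GB", "chr2", 1000 + 10 * j, 1020 + 10 * j)
                for j in range(12)]
        fc = pd.Series(0.0, index=[g.guide_id for g in lib])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = gpr.run_sample(fc, lib, segments, sample="s")
        small = result.guide_table.set_index("guide_id").loc["sgs0"]
        assert bool(small["assigned"])
        assert small["segment_id"] == "chr2:0-1000"
        seg_table = result.segment_table.set_index("segment_id")
        assert not bool(seg_table.loc["chr2:0-1000", "eligible"])

    def test_fixture_bias_removed_from_ratio_correlation(self, pipeline):
        """Corrected gene fold changes decouple from the copy-number ratio."""
        gt = pipeline["screen"].ground_truth
        orig = pipeline["gene_original"]
        corr = pipeline["gene_corrected"]
        ratio = gt.loc[orig.index, "ratio"]
        r_orig = np.corrcoef(orig, ratio)[0, 1]
        r_corr = np.corrcoef(corr, ratio)[0, 1]
        assert abs(r_orig) > 0.5
        assert abs(r_corr) < 0.15

    def test_per_sample_isolation(self, pipeline):
        """Refitting on the same sample vector alone reproduces the result."""
        genome = pipeline["genome"]
        fc = pipeline["guide_fc"]
        res2 = gpr.run_sample(fc, genome.library, genome.segments,
                              sample=pipeline["config"].cell_line)
        np.testing.assert_array_equal(
            pipeline["result"].guide_table["corrected_fc"].to_numpy(),
            res2.guide_table["corrected_fc"].to_numpy(),
        )
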