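"""Stage splitting, optimal change-point segmentation, and cluster statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from femurshift import (
    ChangePointSegmenter,
    TrialDesign,
    analyze_trial,
    cluster_variance,
    generate_gear_trajectory,
    generate_torque_trace,
    odc_segment,
    pair_distances,
    rank_clusters,
    split_stages,
)
from femurshift.gearshift import ClusterSummary


def exhaustive_segmentation(points: np.ndarray, k: int):
    """Enumerate every k-segmentation; return (best boundaries, best cost).

    Boundary tuples are visited in lexicographic order and ties keep the
    first optimum, matching the earliest-boundary convention.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)

    def seg_cost(i, j):
        seg = points[i : j + 1]
        return float(np.sum((seg - seg.mean(axis=0)) ** 2))

    best, best_cost = None, np.inf
    for bounds in itertools.combinations(range(n - 1), k - 1):
        cuts = [-1, *bounds, n - 1]
        cost = sum(seg_cost(cuts[m] + 1, cuts[m + 1]) for m in range(k))
        if cost < best_cost - 1e-12:
            best, best_cost = list(bounds), cost
    return best, best_cost


class TestSplitStages:
    def test_literal_rule_example(self):
        trace = [0, 0.3, 0.6, 0.9, 0.6, 0.3, 0.04, 0]
        stages = split_stages(np.array(trace))
        assert stages.peak_frame == 3
        assert list(stages.contraction) == [0, 1, 2, 3]
        assert list(stages.relaxation) == [4, 5]
        assert list(stages.rest) == [6, 7]

    def test_plateau_peak_tie_break_first(self):
        stages = split_stages(np.array([0, 0.9, 0.9, 0]))
        assert stages.peak_frame == 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="no peak"):
            split_stages(np.zeros(10))

    def test_peak_at_last_frame_warns_no_relaxation(self):
        with pytest.warns(UserWarning, match="no relaxation"):
            stages = split_stages(np.array([0, 0.3, 0.9]))
        assert len(stages.relaxation) == 0

    def test_never_below_threshold_leaves_rest_empty(self):
        with pytest.warns(UserWarning, match="never drops"):
            stages = split_stages(np.array([0, 0.9, 0.5, 0.4]))
        assert len(stages.rest) == 0
        assert list(stages.relaxation) == [2, 3]


class TestOdcSegment:
    def test_exact_piecewise_constant(self):
        x = np.array([0, 0, 0, 5, 5, 5, 10, 10, 10], dtype=float)
        pts = np.column_stack([x, np.zeros_like(x)])
        seg = odc_segment(pts, 3)
        assert seg.boundaries == [2, 5]
        assert seg.cost == pytest.approx(0.0, abs=1e-12)

    def test_constant_series_earliest_boundaries(self):
        seg = odc_segment(np.ones((8, 2)), 3)
        assert seg.boundaries == [0, 1]
        assert seg.cost == pytest.approx(0.0, abs=1e-12)

    def test_random_2d_series_matches_enumeration(self, rng):
        pts = rng.normal(size=(14, 2))
        seg = odc_segment(pts, 3)
        exp_bounds, exp_cost = exhaustive_segmentation(pts, 3)
        assert seg.boundaries == exp_bounds
        assert seg.cost == pytest.approx(exp_cost, rel=1e-10)

    @pytest.mark.parametrize("n,k", [(6, 2), (10, 3), (16, 4), (5, 5)])
    def test_matches_enumeration_across_sizes(self, n, k, rng):
        pts = rng.normal(size=(n, 2))
        seg = odc_segment(pts, k)
        exp_bounds, exp_cost = exhaustive_segmentation(pts, k)
        assert seg.boundaries == exp_bounds
        assert seg.cost == pytest.approx(exp_cost, rel=1e-10)

    def test_k_exceeding_samples_rejected(self):
        with pytest.raises(ValueError):
            odc_segment(np.zeros((3, 2)), 4)

    def test_cost_monotone_in_k(self, rng):
        pts = rng.normal(size=(20, 2))
        costs = [odc_segment(pts, k).cost for k in range(1, 7)]
        assert all(a >= b - 1e-9 for a, b in zip(costs, costs[1:]))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 2**16), shift=st.floats(-50, 50), scale=st.floats(0.1, 10))
    def test_shift_invariance_and_scale_covariance(self, seed, shift, scale):
        pts = np.random.default_rng(seed).normal(size=(12, 2))
        base = odc_segment(pts, 3)
        shifted = odc_segment(pts + shift, 3)
        scaled = odc_segment(pts * scale, 3)
        assert shifted.boundaries == base.boundaries
        assert scaled.boundaries == base.boundaries
        assert scaled.cost == pytest.approx(base.cost * scale**2, rel=1e-6, abs=1e-9)


class TestChangePointSegmenterEstimator:
    def test_labels_partition_samples(self, rng):
        pts = rng.normal(size=(15, 2))
        seg = ChangePointSegmenter(n_segments=3).fit(pts)
        assert seg.labels_.shape == (15,)
        assert set(seg.labels_) == {0, 1, 2}
        for b in seg.boundaries_:
            assert seg.labels_[b] + 1 == seg.labels_[b + 1]

    def test_clone_roundtrip(self):
        from sklearn.base import clone

        est = ChangePointSegmenter(n_segments=4)
        assert clone(est).get_params()["n_segments"] == 4


class TestClusterVariance:
    def test_identical_points_zero(self):
        assert cluster_variance(np.ones((5, 2))) == 0.0

    def test_two_points_population_variance(self):
        assert cluster_variance(np.array([[0.0, 0.0], [2.0, 0.0]])) == pytest.approx(1.0)

    def test_matches_covariance_trace_oracle(self, rng):
        pts = rng.normal(size=(17, 2))
        mean = pts.mean(axis=0)
        trace = float(np.sum((pts - mean) ** 2) / len(pts))
        assert cluster_variance(pts) == pytest.approx(trace, abs=1e-12)

    def test_single_point_missing(self):
        assert np.isnan(cluster_variance(np.zeros((1, 2))))


class TestRankClusters:
    @pytest.mark.parametrize(
        "variances,expected",
        [
            ((15.4, 18.7, 3.9), ["Medium", "Large", "Small"]),
            ((3.9, 26.8, 76.5), ["Small", "Medium", "Large"]),
            ((4.0, 31.7, 4.0), ["Small", "Large", "Medium"]),  # temporal tie-break
        ],
    )
    def test_rank_assignment(self, variances, expected):
        assert rank_clusters(variances) == expected

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            rank_clusters([1.0, 2.0])


def summary(label, mean):
    return ClusterSummary(
        label=label, stage="", frame_start=0, frame_stop=0, n_points=1,
        mean=mean, variance=0.0,
    )


class TestPairDistances:
    def test_identical_means_zero(self):
        s = {lab: summary(lab, (1.0, 1.0)) for lab in ("#A", "#B", "#C", "#C'", "#B'", "#A'")}
        assert all(v == 0.0 for v in pair_distances(s).values())

    def test_three_four_five(self):
        s = {lab: summary(lab, (0.0, 0.0)) for lab in ("#A", "#B", "#C", "#C'", "#B'")}
        s["#A'"] = summary("#A'", (3.0, 4.0))
        assert pair_distances(s)["#A-#A'"] == pytest.approx(5.0)

    def test_missing_cluster_gives_nan(self):
        s = {lab: summary(lab, (0.0, 0.0)) for lab in ("#A", "#B", "#C")}
        d = pair_distances(s)
        assert all(np.isnan(v) for v in d.values())


class TestAnalyzeTrial:
    def test_noiseless_instant_jumps_recover_exact_change_points(self):
        d = TrialDesign(torque_noise_sd=0.0, dwell_noise_sd=(0.0,) * 6, transition_frames=0)
        torque = generate_torque_trace(d)
        track, truth = generate_gear_trajectory(d)
        report = analyze_trial(track, torque)
        assert report.change_points["contraction"] == truth.true_change_points["contraction"]
        assert report.change_points["relaxation"] == truth.true_change_points["relaxation"]

    def test_configured_relaxation_sd_order_is_recovered(self):
        # relaxation jitter ordered B' > C' > A' with clear separation
        d = TrialDesign(seed=11, dwell_noise_sd=(0.2, 0.2, 0.2, 0.3, 0.6, 0.1))
        torque = generate_torque_trace(d)
        track, _ = generate_gear_trajectory(d)
        report = analyze_trial(track, torque)
        v = {lab: report.clusters[lab].variance for lab in ("#C'", "#B'", "#A'")}
        assert v["#B'"] > v["#C'"] > v["#A'"]
        assert report.clusters["#B'"].rank == "Large"

    def test_track_torque_length_mismatch_rejected(self):
        d = TrialDesign()
        track, _ = generate_gear_trajectory(d)
        with pytest.raises(ValueError, match="239"):
            analyze_trial(track, np.zeros(239))

    def test_deterministic_report(self):
        d = TrialDesign(seed=7)
        torque = generate_torque_trace(d)
        track, _ = generate_gear_trajectory(d)
        r1 = analyze_trial(track, torque)
        r2 = analyze_trial(track, torque)
        assert r1.to_dict() == r2.to_dict()

    def test_short_stage_reported_unsegmentable(self):
        from femurshift.tracking import CentroidTrack

        torque = np.array([0, 0.5, 0.9, 0.5, 0.2, 0.04, 0.0, 0.0])
        track = CentroidTrack(
            frames=np.arange(8),
            x=np.arange(8, dtype=float),
            y=np.zeros(8),
            missing=np.zeros(8, bool),
        )
        report = analyze_trial(track, torque)
        assert any("unsegmentable" in w for w in report.warnings)
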