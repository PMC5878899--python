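"""Gear-shift analysis of a femur centroid trajectory.

The trial is split into contraction / relaxation / rest stages from the
torque trace, each working stage is cut into a fixed number of phases by
globally optimal least-squares change-point segmentation (ODC), and the
phases are summarized by their positional variance (a proxy for femur
moving speed), a Small/Medium/Large rank within the stage, and the
Euclidean distances between torque-matched contraction/relaxation pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .tracking import CentroidTrack

CONTRACTION_LABELS = ("#A", "#B", "#C")
RELAXATION_LABELS = ("#C'", "#B'", "#A'")  # temporal order within relaxation
PAIR_LABELS = ("#A-#A'", "#B-#B'", "#C-#C'")
RANKS = ("Small", "Medium", "Large")


@dataclass
class StagePartition:
    """Frame ranges (half-open) of the three torque stages.

    contraction = [0, peak]; relaxation = (peak, rest_onset);
    rest = [rest_onset, end).  ``rest_onset`` is None when torque never
    drops below the rest threshold after the peak.
    """

    peak_frame: int
    rest_onset: int | None
    n_frames: int

    @property
    def contraction(self) -> range:
        return range(0, self.peak_frame + 1)

    @property
    def relaxation(self) -> range:
        stop = self.rest_onset if self.rest_onset is not None else self.n_frames
        return range(self.peak_frame + 1, stop)

    @property
    def rest(self) -> range:
        if self.rest_onset is None:
            return range(self.n_frames, self.n_frames)
        return range(self.rest_onset, self.n_frames)


def split_stages(torque: np.ndarray, rest_threshold: float = 0.05) -> StagePartition:
    """Split a trial by its torque trace.

    The peak (first frame attaining the maximum torque) separates
    contraction from relaxation; the rest stage starts at the first
    post-peak frame whose torque falls below ``rest_threshold``.
    """
    torque = np.asarray(torque, dtype=float)
    if torque.size == 0:
        raise ValueError("empty torque trace")
    if np.max(torque) <= 0:
        raise ValueError("no peak: torque trace is never positive")
    peak = int(np.argmax(torque))
    if peak == torque.size - 1:
        warnings.warn("no relaxation stage: torque peaks at the last frame")
        return StagePartition(peak_frame=peak, rest_onset=None, n_frames=torque.size)
    below = np.nonzero(torque[peak + 1 :] < rest_threshold)[0]
    if below.size == 0:
        warnings.warn(
            f"torque never drops below {rest_threshold} after the peak; rest stage is empty"
        )
        rest_onset = None
    else:
        rest_onset = peak + 1 + int(below[0])
    return StagePartition(peak_frame=peak, rest_onset=rest_onset, n_frames=torque.size)


def _segment_cost_table(points: np.ndarray) -> np.ndarray:
    """cost[i, j] = sum of squared deviations from the segment mean over
    points i..j inclusive, summed over coordinates."""
    n = len(points)
    s1 = np.zeros((n + 1, points.shape[1]))
    s2 = np.zeros(n + 1)
    np.cumsum(points, axis=0, out=s1[1:])
    np.cumsum(np.sum(points * points, axis=1), out=s2[1:])
    cost = np.zeros((n, n))
    for i in range(n):
        lengths = np.arange(1, n - i + 1)
        seg_sum = s1[i + 1 :] - s1[i]
        seg_sq = s2[i + 1 :] - s2[i]
        cost[i, i:] = seg_sq - np.sum(seg_sum * seg_sum, axis=1) / lengths
    return np.maximum(cost, 0.0)


@dataclass
class GearSegmentation:
    """Optimal k-segmentation of one stage's ordered samples.

    ``boundaries`` are k-1 interior after-indices: boundary b means the
    segment ends at sample b (0-based, local to the stage's sample list).
    """

    stage: str
    k: int
    boundaries: list[int]
    cost: float


def odc_segment(points: np.ndarray, k: int, stage: str = "") -> GearSegmentation:
    """Globally optimal least-squares segmentation into k contiguous parts.

    Dynamic program over the ordered samples minimizing the within-segment
    sum of squared deviations from segment means (both coordinates).  The
    optimum is exact; on ties the earliest boundaries are preferred (the
    backtracking keeps the first minimizer at every level).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    cost = _segment_cost_table(points)

    # D[m, j]: optimal cost of splitting samples 0..j into m+1 segments
    D = np.full((k, n), np.inf)
    arg = np.zeros((k, n), dtype=int)
    D[0] = cost[0]
    for m in range(1, k):
        for j in range(m, n):
            cand = D[m - 1, m - 1 : j] + cost[m : j + 1, j]
            t = int(np.argmin(cand))  # first minimizer -> earliest boundary
            D[m, j] = cand[t]
            arg[m, j] = t + m - 1
    boundaries = []
    j = n - 1
    for m in range(k - 1, 0, -1):
        j = arg[m, j]
        boundaries.append(int(j))
    boundaries.reverse()
    return GearSegmentation(stage=stage, k=k, boundaries=boundaries, cost=float(D[k - 1, n - 1]))


class ChangePointSegmenter(BaseEstimator):
    """Optimal change-point segmentation as a scikit-learn estimator.

    fit(X) on an ordered (n_samples, n_features) array sets

    boundaries_ : list of n_segments-1 interior after-indices
    cost_ : optimal within-segment sum of squares
    labels_ : segment index per sample
    """

    def __init__(self, n_segments: int = 3):
        self.n_segments = n_segments

    def fit(self, X: np.ndarray, y=None):
        seg = odc_segment(np.asarray(X, dtype=float), self.n_segments)
        self.boundaries_ = seg.boundaries
        self.cost_ = seg.cost
        n = len(np.atleast_2d(X) if np.asarray(X).ndim > 1 else np.asarray(X))
        labels = np.zeros(n, dtype=int)
        for b in seg.boundaries:
            labels[b + 1 :] += 1
        self.labels_ = labels
        return self

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_


def cluster_variance(points: np.ndarray) -> float:
    """Scalar positional variance of a cluster: population variance of x
    plus population variance of y (trace of the 2-D covariance), mm^2.

    Returns NaN for clusters with fewer than 2 points.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if len(points) < 2:
        return float("nan")
    return float(np.sum(np.var(points, axis=0)))


def rank_clusters(variances) -> list[str]:
    """Small/Medium/Large rank per cluster, ascending by variance.

    Exact ties share the order of occurrence (the earlier cluster gets the
    lower rank), via a stable sort.
    """
    variances = np.asarray(variances, dtype=float)
    if variances.size != 3:
        raise ValueError("expected exactly 3 variances")
    order = np.argsort(variances, kind="stable")
    ranks = [""] * 3
    for rank_name, idx in zip(RANKS, order):
        ranks[idx] = rank_name
    return ranks


@dataclass
class ClusterSummary:
    """One gear phase: frames, mean position, scalar variance, rank."""

    label: str
    stage: str
    frame_start: int
    frame_stop: int  # inclusive
    n_points: int
    mean: tuple[float, float]
    variance: float
    rank: str = ""


def pair_distances(summaries: dict[str, ClusterSummary]) -> dict[str, float]:
    """Euclidean distances (mm) between torque-matched cluster pairs.

    #A (contraction beginning) pairs with #A' (relaxation end), #B with
    #B', #C with #C'.  Pairs with a missing cluster get NaN.
    """
    out = {}
    for pair, a, b in zip(PAIR_LABELS, CONTRACTION_LABELS, RELAXATION_LABELS[::-1]):
        ca, cb = summaries.get(a), summaries.get(b)
        if ca is None or cb is None:
            out[pair] = float("nan")
        else:
            out[pair] = float(np.hypot(ca.mean[0] - cb.mean[0], ca.mean[1] - cb.mean[1]))
    return out


@dataclass
class GearReport:
    """Full per-trial gear-shift analysis result."""

    stages: StagePartition
    segmentations: dict[str, GearSegmentation]
    change_points: dict[str, list[int]]  # absolute frame indices (after-index)
    clusters: dict[str, ClusterSummary]
    distances: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stages": {
                "peak_frame": self.stages.peak_frame,
                "rest_onset": self.stages.rest_onset,
                "n_frames": self.stages.n_frames,
            },
            "change_points": self.change_points,
            "clusters": {
                label: {
                    "stage": c.stage,
                    "frame_start": c.frame_start,
                    "frame_stop": c.frame_stop,
                    "n_points": c.n_points,
                    "mean_x_mm": c.mean[0],
                    "mean_y_mm": c.mean[1],
                    "variance_mm2": c.variance,
                    "rank": c.rank,
                }
                for label, c in self.clusters.items()
            },
            "pair_distances_mm": self.distances,
            "warnings": self.warnings,
        }

    def variance_table(self) -> pd.DataFrame:
        """Per-cluster variance and rank (one row per cluster)."""
        rows = [
            {
                "cluster": label,
                "stage": c.stage,
                "variance_mm2": c.variance,
                "rank": c.rank,
            }
            for label, c in self.clusters.items()
        ]
        return pd.DataFrame(rows)

    def distance_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"pair": k, "euclidean_distance_mm": v} for k, v in self.distances.items()]
        )


def _analyze_stage(
    track: CentroidTrack,
    frame_range: range,
    k: int,
    stage: str,
    labels: tuple[str, ...],
    report_warnings: list[str],
) -> tuple[GearSegmentation | None, list[int], dict[str, ClusterSummary]]:
    frames = np.array([f for f in frame_range], dtype=int)
    if frames.size == 0:
        report_warnings.append(f"{stage}: empty stage")
        return None, [], {}
    sel = np.isin(track.frames, frames)
    ok = sel & ~track.missing
    pts = np.column_stack([track.x[ok], track.y[ok]])
    idx = track.frames[ok]
    if len(pts) < k:
        report_warnings.append(f"{stage}: unsegmentable ({len(pts)} usable frames < k={k})")
        return None, [], {}
    seg = odc_segment(pts, k, stage=stage)
    change_points = [int(idx[b]) for b in seg.boundaries]

    clusters: dict[str, ClusterSummary] = {}
    starts = [0] + [b + 1 for b in seg.boundaries]
    stops = seg.boundaries + [len(pts) - 1]
    variances = []
    for label, s, e in zip(labels, starts, stops):
        seg_pts = pts[s : e + 1]
        var = cluster_variance(seg_pts)
        variances.append(var)
        clusters[label] = ClusterSummary(
            label=label,
            stage=stage,
            frame_start=int(idx[s]),
            frame_stop=int(idx[e]),
            n_points=len(seg_pts),
            mean=(float(seg_pts[:, 0].mean()), float(seg_pts[:, 1].mean())),
            variance=var,
        )
    ranks = rank_clusters(variances)
    for label, rank in zip(labels, ranks):
        clusters[label].rank = rank
    return seg, change_points, clusters


def analyze_trial(
    track: CentroidTrack,
    torque: np.ndarray,
    k: int = 3,
    rest_threshold: float = 0.05,
) -> GearReport:
    """End-to-end gear-shift analysis of one trial.

    Splits the trial by torque, runs ODC (k phases) on the contraction and
    relaxation stages separately (the rest stage is excluded), labels the
    phases temporally (#A, #B, #C then #C', #B', #A'), and computes
    per-phase variances, Small/Medium/Large ranks, and torque-matched pair
    distances.  Missing centroids are dropped (frame indices preserved)
    before segmentation.
    """
    torque = np.asarray(torque, dtype=float)
    if len(track) != torque.size:
        raise ValueError(
            f"track has {len(track)} frames but torque has {torque.size} samples"
        )
    report_warnings: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        stages = split_stages(torque, rest_threshold)
    report_warnings.extend(str(w.message) for w in caught)

    segmentations: dict[str, GearSegmentation] = {}
    change_points: dict[str, list[int]] = {}
    clusters: dict[str, ClusterSummary] = {}
    for stage, frame_range, labels in (
        ("contraction", stages.contraction, CONTRACTION_LABELS),
        ("relaxation", stages.relaxation, RELAXATION_LABELS),
    ):
        seg, cps, cl = _analyze_stage(track, frame_range, k, stage, labels, report_warnings)
        if seg is not None:
            segmentations[stage] = seg
            change_points[stage] = cps
            clusters.update(cl)
    distances = pair_distances(clusters)
    return GearReport(
        stages=stages,
        segmentations=segmentations,
        change_points=change_points,
        clusters=clusters,
        distances=distances,
        warnings=report_warnings,
    )
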