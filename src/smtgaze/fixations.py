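"""Dispersion-style fixation extraction from binocular gaze streams.

Candidate fixations are grown by greedy temporal chaining over the
combined (left/right mean) gaze point: a valid sample joins the open
cluster while it stays within ``max_step`` pixels of the immediately
preceding sample of the cluster and within ``max_gap`` seconds of it;
otherwise the cluster closes and a new one opens. A closed cluster is
retained as a fixation only if all five selection constraints hold:

1. duration (first to last sample timestamp) of at least ``min_duration``;
2. at least ``min_points`` samples;
3. every chained step shorter than ``max_step`` pixels (enforced during
   clustering);
4. left-eye centroid within ``max_inter_eye`` pixels of the right-eye
   centroid;
5. position scatter (RMS of the per-axis standard deviations of the
   combined points about their mean) no greater than ``max_position_sd``.

Saccades are the gaps between consecutive retained fixations: duration is
the start of the current fixation minus the end of the previous one, and
distance is the Euclidean separation of their centroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .streams import SAMPLE_PERIOD, GazeStream, StreamError


@dataclass(frozen=True)
class FixationParams:
    """Fixation selection thresholds (pixels / seconds)."""

    min_duration: float = 0.100
    min_points: int = 5
    max_step: float = 64.0
    max_inter_eye: float = 100.0
    max_position_sd: float = 100.0
    #: a time gap longer than this closes the open cluster (dropped or
    #: invalid samples do not break a cluster by themselves)
    max_gap: float = 3.0 * SAMPLE_PERIOD

    def __post_init__(self) -> None:
        for name in ("min_duration", "min_points", "max_step", "max_inter_eye",
                     "max_position_sd", "max_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Fixation:
    start_ts: float
    end_ts: float
    left_centroid: tuple[float, float]
    right_centroid: tuple[float, float]
    centroid: tuple[float, float]
    n_points: int
    position_sd: float
    #: member samples (ts, combined x, combined y) kept for rendering
    points: np.ndarray = field(repr=False)

    @property
    def duration(self) -> float:
        return self.end_ts - self.start_ts

    @property
    def inter_eye_distance(self) -> float:
        return math.dist(self.left_centroid, self.right_centroid)


@dataclass(frozen=True)
class Saccade:
    duration: float
    distance: float


@dataclass
class CandidateCluster:
    """A chained run of valid samples, before the selection constraints."""

    ts: np.ndarray
    left: np.ndarray  # (n, 2)
    right: np.ndarray  # (n, 2)

    @property
    def combined(self) -> np.ndarray:
        return (self.left + self.right) / 2.0

    @property
    def duration(self) -> float:
        return float(self.ts[-1] - self.ts[0])

    @property
    def n_points(self) -> int:
        return len(self.ts)


def position_sd(points: np.ndarray) -> float:
    """Scatter of a point cloud: RMS of the per-axis standard deviations
    about the mean, one scalar in pixels."""
    if len(points) == 0:
        return 0.0
    var = points.var(axis=0)  # population variance per axis
    return float(np.sqrt(var.mean()))


def cluster_samples(stream: GazeStream, params: FixationParams) -> list[CandidateCluster]:
    """Greedy temporal chaining of valid samples into candidate clusters.

    The chain criterion uses the combined point of each sample against the
    combined point of the immediately preceding sample in the cluster (not
    the running centroid). Invalid samples are skipped; a time gap longer
    than ``params.max_gap`` between consecutive valid samples closes the
    open cluster.
    """
    if len(stream) > 1 and np.any(np.diff(stream.ts) <= 0):  # defensive; ctor enforces
        raise StreamError("gaze timestamps must be strictly increasing")
    idx = np.flatnonzero(stream.valid)
    clusters: list[CandidateCluster] = []
    if len(idx) == 0:
        return clusters

    cx, cy = stream.combined_x, stream.combined_y
    open_idx: list[int] = [int(idx[0])]
    for i in map(int, idx[1:]):
        j = open_idx[-1]
        gap = stream.ts[i] - stream.ts[j]
        step = math.hypot(cx[i] - cx[j], cy[i] - cy[j])
        if gap <= params.max_gap and step < params.max_step:
            open_idx.append(i)
        else:
            clusters.append(_make_cluster(stream, open_idx))
            open_idx = [i]
    clusters.append(_make_cluster(stream, open_idx))
    return clusters


def _make_cluster(stream: GazeStream, indices: list[int]) -> CandidateCluster:
    ii = np.asarray(indices, dtype=int)
    return CandidateCluster(
        ts=stream.ts[ii].copy(),
        left=np.column_stack((stream.left_x[ii], stream.left_y[ii])),
        right=np.column_stack((stream.right_x[ii], stream.right_y[ii])),
    )


def accept_cluster(cluster: CandidateCluster, params: FixationParams) -> Fixation | None:
    """Apply the selection constraints to a candidate cluster."""
    if cluster.duration < params.min_duration:
        return None
    if cluster.n_points < params.min_points:
        return None
    lc = cluster.left.mean(axis=0)
    rc = cluster.right.mean(axis=0)
    if math.dist(lc, rc) > params.max_inter_eye:
        return None
    comb = cluster.combined
    sd = position_sd(comb)
    if sd > params.max_position_sd:
        return None
    cc = comb.mean(axis=0)
    return Fixation(
        start_ts=float(cluster.ts[0]),
        end_ts=float(cluster.ts[-1]),
        left_centroid=(float(lc[0]), float(lc[1])),
        right_centroid=(float(rc[0]), float(rc[1])),
        centroid=(float(cc[0]), float(cc[1])),
        n_points=cluster.n_points,
        position_sd=sd,
        points=np.column_stack((cluster.ts, comb)),
    )


def extract_fixations(stream: GazeStream, params: FixationParams | None = None) -> list[Fixation]:
    """Extract fixations satisfying all five selection constraints."""
    params = params or FixationParams()
    out = []
    for cluster in cluster_samples(stream, params):
        fix = accept_cluster(cluster, params)
        if fix is not None:
            out.append(fix)
    return out


def compute_saccades(fixations: Sequence[Fixation]) -> list[Saccade]:
    """Inter-fixation saccades: n-1 saccades for n time-ordered fixations."""
    starts = [f.start_ts for f in fixations]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("fixations must be time-ordered")
    out = []
    for prev, cur in zip(fixations, fixations[1:]):
        out.append(
            Saccade(
                duration=cur.start_ts - prev.end_ts,
                distance=math.dist(prev.centroid, cur.centroid),
            )
        )
    return out


@dataclass(frozen=True)
class InclusionReport:
    included: tuple[str, ...]
    excluded: tuple[str, ...]
    reasons: Mapping[str, str]


def subject_inclusion(
    fixation_counts: Mapping[str, int],
    min_fixations: int = 10,
) -> InclusionReport:
    """Partition subjects by recorded-fixation count.

    Subjects with fewer than ``min_fixations`` total fixations across the
    session are excluded (limited usable eye-tracking data, e.g. from bad
    calibration or corrective glasses), with a reason per exclusion.
    """
    included, excluded, reasons = [], [], {}
    for subject, n in fixation_counts.items():
        if n < min_fixations:
            excluded.append(subject)
            reasons[subject] = f"only {n} fixations recorded (minimum {min_fixations})"
        else:
            included.append(subject)
    return InclusionReport(tuple(included), tuple(excluded), reasons)
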