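"""Video-level aggregative-tendency statistic.

The assay condenses each video to a single number: the arithmetic mean of
all pairwise Euclidean distances between individuals, pooled over the
retained frames, then natural-log transformed.  Smaller values mean the
group stayed closer together (higher aggregative tendency).

The raw track is first subsampled from the extraction cadence (15 s) to the
analysis cadence (180 s), then the leading acclimation frames — positions
that reflect experimental placement and handling agitation rather than
behaviour — are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .arena import Frame, SamplingScheme, VideoTrack
from .errors import (
    DegenerateTrackError,
    EmptyTrackError,
    InvalidFrameError,
    SamplingError,
)

__all__ = [
    "AggregationSummary",
    "pairwise_distances",
    "subsample_frames",
    "trim_acclimation",
    "summarize_video",
]

#: tolerance (s) when checking that raw frame spacing matches the scheme
SPACING_TOL_S = 0.5


@dataclass
class AggregationSummary:
    """One video's aggregation statistic.

    ``per_frame_means`` holds (time_s, mean distance cm) for every retained
    frame, for time-series plots of how group spread evolves.
    ``log_defined`` is False when every individual was coincident in every
    frame, in which case ``log_mean_pairwise_distance`` is NaN rather than
    silently -inf.
    """

    video_id: str
    n_individuals: int
    n_frames_used: int
    mean_pairwise_distance: float
    log_mean_pairwise_distance: float
    per_frame_means: list[tuple[float, float]] = field(default_factory=list)
    log_defined: bool = True
    arena_diameter_cm: float | None = None
    metadata: dict = field(default_factory=dict)


def pairwise_distances(frame: Frame) -> np.ndarray:
    """All n(n-1)/2 Euclidean distances between individuals in one frame.

    Order is deterministic: pair (i, j) with i < j in lexicographic order,
    i.e. (0,1), (0,2), ..., (0,n-1), (1,2), ...
    """
    if frame.n_individuals < 2:
        raise InvalidFrameError(
            f"pairwise distances need >= 2 positions, got {frame.n_individuals}"
        )
    return pdist(frame.positions)


def subsample_frames(track: VideoTrack, scheme: SamplingScheme) -> VideoTrack:
    """Reduce a raw-cadence track to the analysis cadence.

    Retains frames at offsets 0, analysis_interval, 2x analysis_interval, ...
    from the first frame.  The raw spacing must match
    ``scheme.raw_interval_s`` within 0.5 s; irregular spacing is an error
    naming the offending frame.
    """
    times = track.times_s
    if len(times) > 1:
        gaps = np.diff(times)
        bad = np.flatnonzero(np.abs(gaps - scheme.raw_interval_s) > SPACING_TOL_S)
        if bad.size:
            i = int(bad[0])
            raise SamplingError(
                f"track {track.video_id!r}: spacing between frames {i} and {i + 1} "
                f"is {gaps[i]:.3f} s, expected {scheme.raw_interval_s} s"
            )
    kept = track.frames[:: scheme.stride]
    return VideoTrack(track.video_id, track.arena, list(kept), dict(track.metadata))


def trim_acclimation(track: VideoTrack, scheme: SamplingScheme) -> VideoTrack:
    """Discard the leading acclimation frames from an analysis-cadence track."""
    k = scheme.acclimation_frames
    if k >= track.n_frames:
        raise EmptyTrackError(
            f"track {track.video_id!r}: discarding {k} acclimation frames leaves "
            f"nothing of {track.n_frames}"
        )
    return VideoTrack(track.video_id, track.arena, track.frames[k:], dict(track.metadata))


def summarize_video(
    track: VideoTrack,
    scheme: SamplingScheme,
    *,
    allow_partial: bool = False,
) -> AggregationSummary:
    """Full per-video pipeline: subsample, trim acclimation, pool distances.

    The statistic is the pooled mean over *all* retained pairwise distances;
    because every frame has the same number of individuals this equals the
    mean of per-frame mean distances.

    With ``allow_partial=True`` frames containing a non-finite position are
    dropped with a warning (never imputed); by default they are an error.
    """
    track.validate(allow_nan=allow_partial)
    work = trim_acclimation(subsample_frames(track, scheme), scheme)

    frames = work.frames
    if allow_partial:
        complete = [f for f in frames if np.isfinite(f.positions).all()]
        if len(complete) < len(frames):
            warnings.warn(
                f"track {track.video_id!r}: dropped {len(frames) - len(complete)} "
                f"frame(s) with missing positions",
                stacklevel=2,
            )
        frames = complete
        if not frames:
            raise EmptyTrackError(
                f"track {track.video_id!r}: no complete frames remain"
            )

    per_frame = [(f.time_s, float(pairwise_distances(f).mean())) for f in frames]
    # constant pair count per frame: pooled mean == mean of frame means
    mean_d = float(np.mean([m for _, m in per_frame]))

    log_defined = mean_d > 0.0
    if not log_defined:
        warnings.warn(
            f"track {track.video_id!r}: all individuals coincident in every frame; "
            f"log statistic undefined",
            stacklevel=2,
        )
    log_d = float(np.log(mean_d)) if log_defined else float("nan")

    return AggregationSummary(
        video_id=track.video_id,
        n_individuals=work.n_individuals,
        n_frames_used=len(frames),
        mean_pairwise_distance=mean_d,
        log_mean_pairwise_distance=log_d,
        per_frame_means=per_frame,
        log_defined=log_defined,
        arena_diameter_cm=track.arena.diameter_cm,
        metadata=dict(track.metadata),
    )


def require_log(summary: AggregationSummary) -> float:
    """Return the log statistic, raising if it is undefined."""
    if not summary.log_defined:
        raise DegenerateTrackError(
            f"video {summary.video_id!r}: log mean pairwise distance undefined "
            f"(mean distance is 0)"
        )
    return summary.log_mean_pairwise_distance
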