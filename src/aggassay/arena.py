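"""Core containers: circular arena, frames, video tracks, sampling scheme.

All geometry is in centimetres, Cartesian coordinates with the origin at the
arena centre.  A :class:`VideoTrack` is the unit the rest of the pipeline
operates on: an ordered sequence of frames, each holding one position per
individual, plus treatment metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator

import numpy as np

from .errors import AggregationError, InvalidFrameError, ParameterError

#: slack (cm) allowed when checking arena containment; annotated points can
#: sit exactly on the dish wall and suffer float rounding.
CONTAINMENT_TOL = 1e-9


@dataclass(frozen=True)
class Arena:
    """Circular test arena.

    Parameters
    ----------
    diameter_cm
        Dish diameter in cm.  The study dish is a 14.5-cm petri dish.
    """

    diameter_cm: float = 14.5

    def __post_init__(self) -> None:
        if not (self.diameter_cm > 0 and np.isfinite(self.diameter_cm)):
            raise ParameterError(f"arena diameter must be positive, got {self.diameter_cm}")

    @property
    def radius_cm(self) -> float:
        return self.diameter_cm / 2.0

    def contains(self, positions: np.ndarray, tol: float = CONTAINMENT_TOL) -> np.ndarray:
        """Boolean mask: which of the (n, 2) positions lie inside the dish."""
        positions = np.asarray(positions, dtype=float)
        r2 = positions[..., 0] ** 2 + positions[..., 1] ** 2
        return r2 <= (self.radius_cm + tol) ** 2


@dataclass(frozen=True)
class Frame:
    """One video frame: a timestamp and one (x, y) position per individual.

    ``positions`` is an (n, 2) float array; row order is the track's roster
    order and is the individual's identity.
    """

    time_s: float
    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise InvalidFrameError(f"positions must be (n, 2), got shape {pos.shape}")
        if pos.shape[0] == 0:
            raise InvalidFrameError("frame has no positions")
        if self.time_s < 0 or not np.isfinite(self.time_s):
            raise InvalidFrameError(f"frame time must be finite and >= 0, got {self.time_s}")
        object.__setattr__(self, "positions", pos)

    @property
    def n_individuals(self) -> int:
        return int(self.positions.shape[0])


@dataclass
class VideoTrack:
    """Time-ordered positions of a fixed roster of individuals in one arena.

    Invariants (checked by :meth:`validate`): frames strictly increasing in
    time, constant individual count >= 2, all positions inside the arena.
    ``metadata`` carries open experiment annotations (developmental stage,
    population, latitude, species, relatedness treatment, ...).
    """

    video_id: str
    arena: Arena
    frames: list[Frame]
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        if not self.frames:
            raise AggregationError(f"track {self.video_id!r} has no frames")
        return self.frames[0].n_individuals

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times_s(self) -> np.ndarray:
        return np.array([f.time_s for f in self.frames], dtype=float)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def validate(self, allow_nan: bool = False) -> "VideoTrack":
        """Check all track invariants; return self for chaining."""
        if not self.frames:
            raise AggregationError(f"track {self.video_id!r} has no frames")
        n = self.frames[0].n_individuals
        if n < 2:
            raise InvalidFrameError(
                f"track {self.video_id!r} needs >= 2 individuals, got {n}"
            )
        prev_t = -np.inf
        for i, fr in enumerate(self.frames):
            if fr.n_individuals != n:
                raise InvalidFrameError(
                    f"track {self.video_id!r} frame {i}: expected {n} individuals, "
                    f"got {fr.n_individuals}"
                )
            if fr.time_s <= prev_t:
                raise InvalidFrameError(
                    f"track {self.video_id!r} frame {i}: time {fr.time_s} s not "
                    f"strictly increasing (previous {prev_t} s)"
                )
            prev_t = fr.time_s
            finite = np.isfinite(fr.positions)
            if not finite.all():
                if not allow_nan:
                    raise InvalidFrameError(
                        f"track {self.video_id!r} frame {i}: non-finite position"
                    )
                continue
            inside = self.arena.contains(fr.positions)
            if not inside.all():
                j = int(np.flatnonzero(~inside)[0])
                x, y = fr.positions[j]
                raise InvalidFrameError(
                    f"track {self.video_id!r} frame {i}: individual {j} at "
                    f"({x:.6g}, {y:.6g}) outside {self.arena.diameter_cm}-cm arena"
                )
        return self

    def positions_array(self) -> np.ndarray:
        """Stack all frames into an (n_frames, n_individuals, 2) array."""
        return np.stack([f.positions for f in self.frames])


@dataclass(frozen=True)
class SamplingScheme:
    """Frame-extraction and analysis cadence.

    Defaults reproduce the study protocol: 90-min recording, one raw frame
    every 15 s (360 frames), analysis at one frame per 180 s (30 frames),
    first 12 analysed frames (2,160 s) discarded as acclimation, leaving 18.
    """

    raw_interval_s: float = 15.0
    analysis_interval_s: float = 180.0
    acclimation_frames: int = 12
    duration_s: float = 5400.0

    def __post_init__(self) -> None:
        if self.raw_interval_s <= 0 or self.analysis_interval_s <= 0:
            raise ParameterError("sampling intervals must be positive")
        ratio = self.analysis_interval_s / self.raw_interval_s
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ParameterError(
                f"analysis interval ({self.analysis_interval_s} s) must be a "
                f"positive integer multiple of the raw interval ({self.raw_interval_s} s)"
            )
        if self.acclimation_frames < 0:
            raise ParameterError("acclimation_frames must be >= 0")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if self.acclimation_frames >= self.n_analyzed_frames:
            raise ParameterError(
                f"acclimation ({self.acclimation_frames} frames) leaves no analysed "
                f"frames out of {self.n_analyzed_frames}"
            )

    @property
    def stride(self) -> int:
        """Raw frames per analysed frame."""
        return int(round(self.analysis_interval_s / self.raw_interval_s))

    @property
    def n_raw_frames(self) -> int:
        """Raw frames in a full recording (frame at t=0 included)."""
        return int(self.duration_s // self.raw_interval_s)

    @property
    def n_analyzed_frames(self) -> int:
        """Frames retained after subsampling a full recording."""
        return int(np.ceil(self.n_raw_frames / self.stride))

    @property
    def n_retained_frames(self) -> int:
        """Analysed frames remaining after the acclimation discard."""
        return self.n_analyzed_frames - self.acclimation_frames
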