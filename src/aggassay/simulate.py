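"""Synthetic larval-movement generator with tunable aggregation.

Real videos from the assay are not publicly available, so this module
produces position tracks whose aggregation strength is a known, monotone
function of a single parameter.  The movement model is deliberately
minimal — a biased random walk, not a mechanistic larva model:

* individuals start equidistant on the dish perimeter, as in the assay;
* each 15-s step combines an isotropic random displacement with a bias
  toward (attraction > 0) or away from (attraction < 0) the centroid of
  neighbours within ``interaction_range_cm`` (falling back to the nearest
  individual when none is in range, so the rule degrades gracefully at
  n = 2);
* the wall reflects: any overshoot past the dish edge is folded back
  radially, which preserves the uniform (CSR) equilibrium of the unbiased
  walk.

At attraction 0 the walk mixes toward a uniform distribution over the dish;
at strong positive attraction groups collapse into a tight cluster; at
strong negative attraction individuals hug opposite walls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .arena import Arena, Frame, SamplingScheme, VideoTrack
from .errors import ParameterError

__all__ = [
    "MovementParams",
    "GroupSpec",
    "ExperimentDesign",
    "place_on_perimeter",
    "simulate_colony",
    "generate_experiment",
]


@dataclass(frozen=True)
class MovementParams:
    """Biased-random-walk parameters.

    attraction
        Dimensionless weight in [-1, 1].  Positive biases movement toward
        neighbours, 0 is a pure random walk, negative biases away.
    step_cm
        Mean random step length per raw (15-s) frame.  Default 0.5 cm, on
        the order of a larval body length.
    step_sd_cm
        Spread of the random step length.
    interaction_range_cm
        Distance within which neighbours exert the bias.
    """

    attraction: float = 0.0
    step_cm: float = 0.5
    step_sd_cm: float = 0.25
    interaction_range_cm: float = 10.0

    def __post_init__(self) -> None:
        if not abs(self.attraction) <= 1.0:
            raise ParameterError(f"|attraction| must be <= 1, got {self.attraction}")
        if self.step_cm <= 0:
            raise ParameterError(f"step_cm must be > 0, got {self.step_cm}")
        if self.step_sd_cm < 0:
            raise ParameterError(f"step_sd_cm must be >= 0, got {self.step_sd_cm}")
        if self.interaction_range_cm <= 0:
            raise ParameterError(
                f"interaction_range_cm must be > 0, got {self.interaction_range_cm}"
            )


def place_on_perimeter(n: int, arena: Arena, rng: np.random.Generator) -> Frame:
    """Start frame: n individuals equidistant on the dish wall.

    Consecutive angular gaps are exactly 2*pi/n; the whole ring is given a
    random global rotation.
    """
    if n < 2:
        raise ParameterError(f"need >= 2 individuals, got {n}")
    rot = rng.uniform(0.0, 2.0 * np.pi)
    angles = rot + 2.0 * np.pi * np.arange(n) / n
    r = arena.radius_cm
    pos = np.column_stack([r * np.cos(angles), r * np.sin(angles)])
    return Frame(time_s=0.0, positions=pos)


def _reflect_into_disk(pos: np.ndarray, radius: float) -> np.ndarray:
    """Fold radial overshoot back inside the wall (specular in the radius)."""
    rad = np.hypot(pos[:, 0], pos[:, 1])
    out = rad > radius
    if out.any():
        new_rad = 2.0 * radius - rad[out]
        if (new_rad < 0).any():
            raise ParameterError(
                "step too large to reflect back into the arena; reduce step_cm"
            )
        scale = np.where(rad[out] > 0, new_rad / rad[out], 0.0)
        pos = pos.copy()
        pos[out] *= scale[:, None]
    return pos


def _bias_directions(pos: np.ndarray, interaction_range: float) -> np.ndarray:
    """Unit vectors from each individual toward its neighbour target.

    Target is the centroid of neighbours within range, else the nearest
    individual.  Coincident targets give a zero vector (no bias).
    """
    n = pos.shape[0]
    diff = pos[None, :, :] - pos[:, None, :]          # diff[i, j] = p_j - p_i
    dist = np.hypot(diff[..., 0], diff[..., 1])
    np.fill_diagonal(dist, np.inf)

    targets = np.empty_like(pos)
    for i in range(n):
        in_range = dist[i] <= interaction_range
        if in_range.any():
            targets[i] = pos[in_range].mean(axis=0)
        else:
            targets[i] = pos[int(np.argmin(dist[i]))]
    vec = targets - pos
    norm = np.hypot(vec[:, 0], vec[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norm[:, None] > 0, vec / np.where(norm == 0, 1, norm)[:, None], 0.0)
    return unit


def simulate_colony(
    n: int,
    params: MovementParams,
    arena: Arena,
    scheme: SamplingScheme,
    rng: np.random.Generator,
    video_id: str = "sim",
    metadata: dict[str, Any] | None = None,
) -> VideoTrack:
    """Simulate one video at raw cadence (default 360 frames at 15 s).

    Each step every individual moves by an isotropic random vector of length
    |N(step_cm, step_sd_cm)| plus ``attraction * step_cm`` along the unit
    vector toward its neighbour target; positions reflect at the wall.
    """
    if params.step_cm * (1.0 + abs(params.attraction)) + 5.0 * params.step_sd_cm >= arena.diameter_cm:
        raise ParameterError(
            f"step scale {params.step_cm} cm too large for a "
            f"{arena.diameter_cm}-cm arena"
        )
    n_frames = scheme.n_raw_frames
    start = place_on_perimeter(n, arena, rng)
    pos = start.positions.copy()
    frames = [start]
    for k in range(1, n_frames):
        lengths = np.abs(rng.normal(params.step_cm, params.step_sd_cm, size=n))
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        rand_step = np.column_stack([lengths * np.cos(theta), lengths * np.sin(theta)])
        step = rand_step
        if params.attraction != 0.0:
            step = step + params.attraction * params.step_cm * _bias_directions(
                pos, params.interaction_range_cm
            )
        pos = _reflect_into_disk(pos + step, arena.radius_cm)
        frames.append(Frame(time_s=k * scheme.raw_interval_s, positions=pos.copy()))
    return VideoTrack(video_id, arena, frames, dict(metadata or {}))


@dataclass(frozen=True)
class GroupSpec:
    """One treatment group in a synthetic experiment."""

    label: str
    n_videos: int
    n_individuals: int
    params: MovementParams
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_videos < 1:
            raise ParameterError(f"group {self.label!r}: n_videos must be >= 1")
        if self.n_individuals < 2:
            raise ParameterError(f"group {self.label!r}: need >= 2 individuals")


@dataclass
class ExperimentDesign:
    """A set of treatment groups sharing one arena and sampling scheme."""

    groups: list[GroupSpec]
    arena: Arena = Arena()
    scheme: SamplingScheme = SamplingScheme()
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ParameterError("group labels must be unique")
        if not self.groups:
            raise ParameterError("design has no groups")

    @property
    def n_videos(self) -> int:
        return sum(g.n_videos for g in self.groups)


def generate_experiment(design: ExperimentDesign):
    """Simulate every video in the design.

    Returns ``(tracks, table)`` where ``table`` is a pandas DataFrame with
    columns ``video_id, group, covariate`` (covariate taken from the group
    metadata key ``"latitude"`` when present, else NaN).  Fully reproducible
    from ``design.seed``: each video gets an independent child stream.
    """
    import pandas as pd

    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(design.n_videos)
    tracks: list[VideoTrack] = []
    rows = []
    idx = 0
    seen: set[str] = set()
    for group in design.groups:
        for v in range(group.n_videos):
            vid = f"{group.label}_{v:03d}"
            if vid in seen:
                raise ParameterError(f"duplicate video id {vid!r}")
            seen.add(vid)
            rng = np.random.default_rng(children[idx])
            idx += 1
            meta = {"group": group.label, **group.metadata}
            track = simulate_colony(
                group.n_individuals, group.params, design.arena, design.scheme,
                rng, video_id=vid, metadata=meta,
            )
            tracks.append(track)
            rows.append(
                {
                    "video_id": vid,
                    "group": group.label,
                    "covariate": group.metadata.get("latitude", np.nan),
                }
            )
    return tracks, pd.DataFrame(rows)
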