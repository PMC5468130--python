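"""Random-dispersal (complete spatial randomness) null model.

Under the null hypothesis that larvae neither aggregate nor avoid each
other, each individual's position is independent and uniform over the dish
area.  The reference distribution is built by simulating whole videos under
CSR — mimicking the real sampling procedure frame for frame — and taking
the empirical 95% percentile interval of the simulated per-video mean
pairwise distances.  Observed videos falling below the band are classified
aggregative, above it overdispersed (mutual avoidance), inside it random.

For two uniform points in a disk of radius r the expected distance is
128 r / (45 pi) — about 6.56 cm in the 14.5-cm dish — and by linearity of
expectation the expected *mean* pairwise distance is the same for every
group size; only its spread shrinks as more pairs are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arena import Arena, Frame, SamplingScheme, VideoTrack
from .errors import IncompatibilityError, ParameterError
from .statistic import AggregationSummary, require_log, summarize_video

__all__ = [
    "NullConfig",
    "NullDistribution",
    "NullClassification",
    "expected_csr_pair_distance",
    "sample_uniform_in_disk",
    "simulate_null_video",
    "build_null_distribution",
    "classify_video",
]


def expected_csr_pair_distance(arena: Arena) -> float:
    """Closed-form E[distance] between two independent uniform points in the disk."""
    return 128.0 * arena.radius_cm / (45.0 * np.pi)


@dataclass(frozen=True)
class NullConfig:
    """Settings for one CSR reference distribution.

    Defaults follow the study: 100 simulated videos of 30 frames each, 95%
    interval, 14.5-cm dish.
    """

    n_individuals: int
    arena: Arena = Arena()
    n_videos: int = 100
    n_frames: int = 30
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ParameterError("null model needs >= 2 individuals")
        if self.n_videos < 2:
            raise ParameterError("need >= 2 simulated videos")
        if self.n_frames < 1:
            raise ParameterError("need >= 1 frame per simulated video")
        if not (0.0 < self.ci_level < 1.0):
            raise ParameterError(f"ci_level must be in (0, 1), got {self.ci_level}")


@dataclass
class NullDistribution:
    """Monte Carlo CSR reference for one group size and arena."""

    config: NullConfig
    video_means: np.ndarray  # cm, length n_videos
    ci_lower: float
    ci_upper: float
    grand_mean: float
    seed_used: int

    @property
    def log_band(self) -> tuple[float, float]:
        """The CI band on the natural-log scale used for classification."""
        return float(np.log(self.ci_lower)), float(np.log(self.ci_upper))

    @property
    def log_video_means(self) -> np.ndarray:
        return np.log(self.video_means)


@dataclass(frozen=True)
class NullClassification:
    """Band classification of one observed video (log scale).

    ``label`` is "aggregative" below the band, "overdispersed" above it,
    "random" inside (inclusive).
    """

    label: str
    observed_log_mean: float
    band_log_lower: float
    band_log_upper: float


def sample_uniform_in_disk(arena: Arena, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw positions uniform over the disk *area* (radius ~ r*sqrt(U)).

    Returns an (size, 2) array in cm.
    """
    u = rng.random(size)
    theta = rng.uniform(0.0, 2.0 * np.pi, size)
    r = arena.radius_cm * np.sqrt(u)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def simulate_null_video(
    config: NullConfig,
    rng: np.random.Generator,
    video_id: str = "null",
) -> VideoTrack:
    """One CSR video: each frame an independent uniform placement of the group.

    The track uses the analysis cadence directly (180-s spacing) so it can be
    fed through :func:`summarize_video` with zero acclimation frames — the
    same code path observed videos take.
    """
    frames = []
    for k in range(config.n_frames):
        pos = sample_uniform_in_disk(config.arena, rng, size=config.n_individuals)
        frames.append(Frame(time_s=180.0 * k, positions=pos))
    return VideoTrack(video_id, config.arena, frames, {"source": "csr_null"})


def _null_scheme(config: NullConfig) -> SamplingScheme:
    return SamplingScheme(
        raw_interval_s=180.0,
        analysis_interval_s=180.0,
        acclimation_frames=0,
        duration_s=180.0 * config.n_frames,
    )


def build_null_distribution(config: NullConfig, rng: np.random.Generator | None = None) -> NullDistribution:
    """Simulate ``n_videos`` CSR videos and summarise their mean distances.

    The CI is the empirical percentile interval of the simulated per-video
    means (2.5th/97.5th percentiles at the default 95% level).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    scheme = _null_scheme(config)
    means = np.empty(config.n_videos)
    for v in range(config.n_videos):
        track = simulate_null_video(config, rng, video_id=f"null_{v:05d}")
        means[v] = summarize_video(track, scheme).mean_pairwise_distance
    tail = 100.0 * (1.0 - config.ci_level) / 2.0
    # outward-rounded order statistics so >= ci_level of the simulated means
    # fall inside the band by construction
    lo = np.percentile(means, tail, method="lower")
    hi = np.percentile(means, 100.0 - tail, method="higher")
    return NullDistribution(
        config=config,
        video_means=means,
        ci_lower=float(lo),
        ci_upper=float(hi),
        grand_mean=float(means.mean()),
        seed_used=config.seed,
    )


def classify_log_value(log_value: float, null: NullDistribution) -> NullClassification:
    """Band-classify a log mean pairwise distance against the null CI."""
    lo, hi = null.log_band
    if log_value < lo:
        label = "aggregative"
    elif log_value > hi:
        label = "overdispersed"
    else:
        label = "random"
    return NullClassification(label, float(log_value), lo, hi)


def classify_video(summary: AggregationSummary, null: NullDistribution) -> NullClassification:
    """Classify one observed video against the CSR band (log scale).

    The summary and the null must share group size and arena diameter.
    """
    if summary.n_individuals != null.config.n_individuals:
        raise IncompatibilityError(
            f"video {summary.video_id!r} has {summary.n_individuals} individuals; "
            f"null built for {null.config.n_individuals}"
        )
    if (
        summary.arena_diameter_cm is not None
        and abs(summary.arena_diameter_cm - null.config.arena.diameter_cm) > 1e-9
    ):
        raise IncompatibilityError(
            f"video {summary.video_id!r} recorded in a {summary.arena_diameter_cm}-cm "
            f"arena; null built for {null.config.arena.diameter_cm} cm"
        )
    return classify_log_value(require_log(summary), null)
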