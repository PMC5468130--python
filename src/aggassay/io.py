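"""File formats, run configuration, and the end-to-end pipeline.

All on-disk formats are plain CSV.  Track files have one row per individual
per frame with header ``video_id,frame_index,time_s,larva_id,x_cm,y_cm``.
Every file the pipeline writes starts with comment lines embedding the seed
and a hash of the run configuration, so any output can be reproduced from
its own header.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .arena import Arena, Frame, SamplingScheme, VideoTrack
from .comparison import (
    ComparisonResult,
    GroupedObservations,
    compare_with_null_group,
    continuous_predictor_anova,
)
from .errors import AggregationError, ParameterError, ParseError
from .null import NullConfig, NullDistribution, build_null_distribution
from .statistic import AggregationSummary, summarize_video

logger = logging.getLogger("aggassay")

TRACK_COLUMNS = ["video_id", "frame_index", "time_s", "larva_id", "x_cm", "y_cm"]
SUMMARY_COLUMNS = [
    "video_id",
    "n_individuals",
    "n_frames_used",
    "mean_pairwise_distance_cm",
    "log_mean_pairwise_distance",
]


# ---------------------------------------------------------------------------
# headers / provenance

def config_hash(obj: Any) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_with_header(df: pd.DataFrame, path: Path, header: dict[str, Any]) -> None:
    with open(path, "w") as fh:
        for key, val in header.items():
            fh.write(f"# {key}={val}\n")
        # %.17g guarantees bit-exact float round trips through the CSV
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_header(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


# ---------------------------------------------------------------------------
# track files

def tracks_to_frame(tracks: list[VideoTrack]) -> pd.DataFrame:
    """Flatten tracks to the long track-CSV layout."""
    rows = []
    for track in tracks:
        for fi, fr in enumerate(track.frames):
            for li in range(fr.n_individuals):
                rows.append(
                    (track.video_id, fi, fr.time_s, li,
                     fr.positions[li, 0], fr.positions[li, 1])
                )
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def write_tracks(
    tracks: list[VideoTrack],
    path: str | Path,
    header: dict[str, Any] | None = None,
) -> None:
    _write_with_header(tracks_to_frame(tracks), Path(path), header or {})


def read_tracks(
    path: str | Path,
    arena: Arena | None = None,
    scale_cm_per_unit: float = 1.0,
) -> list[VideoTrack]:
    """Load and validate a track CSV.

    ``scale_cm_per_unit`` converts raw annotation units (e.g. pixels
    calibrated from the known dish diameter) to cm.  Any invariant
    violation — missing column, non-monotone time, varying individual count
    within a video, position outside the arena — is a :class:`ParseError`
    naming the offending data row.
    """
    path = Path(path)
    if arena is None:
        arena = Arena()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    df = df.reset_index().rename(columns={"index": "_row"})
    df["x_cm"] = df["x_cm"] * scale_cm_per_unit
    df["y_cm"] = df["y_cm"] * scale_cm_per_unit

    tracks: list[VideoTrack] = []
    for vid, vdf in df.groupby("video_id", sort=False):
        vdf = vdf.sort_values(["frame_index", "larva_id"], kind="stable")
        roster = sorted(vdf["larva_id"].unique())
        n = len(roster)
        if n < 2:
            raise ParseError(
                f"video {vid!r}: needs >= 2 individuals, found {n}",
                row=int(vdf["_row"].iloc[0]),
            )
        frames: list[Frame] = []
        prev_t = -np.inf
        for fi, fdf in vdf.groupby("frame_index", sort=True):
            if list(fdf["larva_id"]) != roster:
                raise ParseError(
                    f"video {vid!r} frame {fi}: individuals "
                    f"{sorted(fdf['larva_id'])} != roster {roster}",
                    row=int(fdf["_row"].iloc[0]),
                )
            t = float(fdf["time_s"].iloc[0])
            if t <= prev_t:
                raise ParseError(
                    f"video {vid!r} frame {fi}: time {t} s not increasing",
                    row=int(fdf["_row"].iloc[0]),
                )
            prev_t = t
            pos = fdf[["x_cm", "y_cm"]].to_numpy(dtype=float)
            inside = arena.contains(pos)
            if not inside.all():
                j = int(np.flatnonzero(~inside)[0])
                raise ParseError(
                    f"video {vid!r} frame {fi}: position "
                    f"({pos[j, 0]:.6g}, {pos[j, 1]:.6g}) outside "
                    f"{arena.diameter_cm}-cm arena",
                    row=int(fdf["_row"].iloc[j]),
                )
            frames.append(Frame(time_s=t, positions=pos))
        try:
            tracks.append(VideoTrack(str(vid), arena, frames).validate())
        except AggregationError as exc:  # pragma: no cover - belt and braces
            raise ParseError(f"video {vid!r}: {exc}") from exc
    return tracks


# ---------------------------------------------------------------------------
# summaries / design / null CSVs

def summaries_to_frame(summaries: list[AggregationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.video_id, s.n_individuals, s.n_frames_used,
             s.mean_pairwise_distance, s.log_mean_pairwise_distance)
            for s in summaries
        ],
        columns=SUMMARY_COLUMNS,
    )


def write_summaries(
    summaries: list[AggregationSummary],
    path: str | Path,
    header: dict[str, Any] | None = None,
) -> None:
    _write_with_header(summaries_to_frame(summaries), Path(path), header or {})


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), comment="#")
    for col in ("video_id", "group"):
        if col not in df.columns:
            raise ParseError(f"{path}: design file missing column {col!r}")
    if "covariate" not in df.columns:
        df["covariate"] = np.nan
    return df


def write_null(null: NullDistribution, path: str | Path) -> None:
    """Null CSV: one row per simulated video, CI summary in the header."""
    df = pd.DataFrame(
        {
            "replicate": np.arange(len(null.video_means)),
            "mean_pairwise_distance_cm": null.video_means,
        }
    )
    cfg = null.config
    _write_with_header(
        df, Path(path),
        {
            "n_individuals": cfg.n_individuals,
            "diameter_cm": cfg.arena.diameter_cm,
            "n_frames": cfg.n_frames,
            "ci_level": cfg.ci_level,
            "seed": null.seed_used,
            "grand_mean_cm": f"{null.grand_mean:.6f}",
            "ci_lower_cm": f"{null.ci_lower:.6f}",
            "ci_upper_cm": f"{null.ci_upper:.6f}",
        },
    )


def read_null(path: str | Path) -> NullDistribution:
    """Rebuild a NullDistribution from a null CSV written by :func:`write_null`."""
    path = Path(path)
    meta = _read_header(path)
    for key in ("n_individuals", "diameter_cm", "ci_level"):
        if key not in meta:
            raise ParseError(f"{path}: null file header missing {key!r}")
    df = pd.read_csv(path, comment="#")
    means = df["mean_pairwise_distance_cm"].to_numpy(dtype=float)
    cfg = NullConfig(
        n_individuals=int(meta["n_individuals"]),
        arena=Arena(float(meta["diameter_cm"])),
        n_videos=len(means),
        n_frames=int(meta.get("n_frames", 30)),
        ci_level=float(meta["ci_level"]),
        seed=int(meta.get("seed", 0)),
    )
    tail = 100.0 * (1.0 - cfg.ci_level) / 2.0
    lo = np.percentile(means, tail, method="lower")
    hi = np.percentile(means, 100.0 - tail, method="higher")
    return NullDistribution(cfg, means, float(lo), float(hi),
                            float(means.mean()), cfg.seed)


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class RunConfig:
    """Everything one pipeline run needs, recorded in every output header."""

    tracks_path: str
    design_path: str
    out_dir: str
    arena_diameter_cm: float = 14.5
    scheme: SamplingScheme = field(default_factory=SamplingScheme)
    n_null_videos: int = 100
    n_null_frames: int = 30
    ci_level: float = 0.95
    alpha: float = 0.05
    seed: int = 0
    verbosity: str = "INFO"

    def as_dict(self) -> dict[str, Any]:
        d = asdict(self)
        # output location and log level do not affect the results
        d.pop("out_dir", None)
        d.pop("verbosity", None)
        return d

    def hash(self) -> str:
        return config_hash(self.as_dict())


def run_pipeline(config: RunConfig) -> dict[int, ComparisonResult]:
    """Run the whole assay: summarise tracks, build nulls, compare groups.

    Group sizes are analysed separately (larger groups have systematically
    smaller maximum pairwise distances, so sizes are not directly
    comparable): for each distinct number of individuals one CSR null is
    built and the treatment groups of that size are tested against it.
    Writes ``summaries.csv``, ``per_frame_means.csv``, and per-size
    ``null_n{n}.csv``, ``anova_n{n}.csv``, ``tukey_n{n}.csv``,
    ``classification_n{n}.csv`` under ``config.out_dir``.
    """
    logging.basicConfig(level=config.verbosity)
    tracks_path = Path(config.tracks_path)
    design_path = Path(config.design_path)
    for p in (tracks_path, design_path):
        if not p.exists():
            raise ParameterError(f"input file {p} does not exist")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    header = {"seed": config.seed, "config": config.hash()}
    logger.info("run config %s (seed %d)", config.hash(), config.seed)

    arena = Arena(config.arena_diameter_cm)
    tracks = read_tracks(tracks_path, arena=arena)
    design = read_design(design_path)
    group_of = dict(zip(design["video_id"].astype(str), design["group"]))

    summaries = [summarize_video(t, config.scheme) for t in tracks]
    write_summaries(summaries, out_dir / "summaries.csv", header)

    pfm = pd.DataFrame(
        [
            (s.video_id, t, m)
            for s in summaries
            for (t, m) in s.per_frame_means
        ],
        columns=["video_id", "time_s", "mean_pairwise_distance_cm"],
    )
    _write_with_header(pfm, out_dir / "per_frame_means.csv", header)

    results: dict[int, ComparisonResult] = {}
    for n in sorted({s.n_individuals for s in summaries}):
        subset = [s for s in summaries if s.n_individuals == n]
        groups: dict[str, list[float]] = {}
        for s in subset:
            label = group_of.get(s.video_id)
            if label is None:
                raise ParseError(f"video {s.video_id!r} missing from design table")
            groups.setdefault(str(label), []).append(s.log_mean_pairwise_distance)

        null = build_null_distribution(
            NullConfig(
                n_individuals=n, arena=arena,
                n_videos=config.n_null_videos, n_frames=config.n_null_frames,
                ci_level=config.ci_level, seed=config.seed + n,
            )
        )
        write_null(null, out_dir / f"null_n{n}.csv")

        obs = GroupedObservations(groups={k: np.array(v) for k, v in groups.items()})
        if len(obs.groups) >= 1:
            result = compare_with_null_group(obs, null, alpha=config.alpha)
            results[n] = result
            _write_comparison(result, n, out_dir, header)
    logger.info("pipeline complete: %d group-size analyses", len(results))
    return results


def _write_comparison(
    result: ComparisonResult, n: int, out_dir: Path, header: dict[str, Any]
) -> None:
    a = result.anova
    anova_df = pd.DataFrame(
        [
            {
                "F": a.F, "df_between": a.df_between, "df_within": a.df_within,
                "p": a.p, "SS_between": a.SS_between, "SS_within": a.SS_within,
            }
        ]
    )
    _write_with_header(anova_df, out_dir / f"anova_n{n}.csv", header)

    tukey_df = pd.DataFrame(
        [
            {
                "group_a": pr.group_a, "group_b": pr.group_b,
                "mean_difference": pr.mean_difference,
                "p_adjusted": pr.p_adjusted,
                "ci_lower": pr.ci_lower, "ci_upper": pr.ci_upper,
            }
            for pr in result.tukey.pairs
        ]
    )
    _write_with_header(tukey_df, out_dir / f"tukey_n{n}.csv", header)

    cls_df = pd.DataFrame(
        [
            {
                "group": label, "label": c.label,
                "observed_log_mean": c.observed_log_mean,
                "band_log_lower": c.band_log_lower,
                "band_log_upper": c.band_log_upper,
            }
            for label, c in result.classifications.items()
        ]
    )
    _write_with_header(cls_df, out_dir / f"classification_n{n}.csv", header)


def grouped_from_summaries(
    summaries: list[AggregationSummary],
    design: pd.DataFrame,
) -> GroupedObservations:
    """Assemble GroupedObservations (with covariate, if any) from a design table."""
    group_of = dict(zip(design["video_id"].astype(str), design["group"]))
    cov_of = dict(zip(design["video_id"].astype(str), design["covariate"]))
    groups: dict[str, list[float]] = {}
    covs: dict[str, list[float]] = {}
    for s in summaries:
        label = group_of.get(s.video_id)
        if label is None:
            raise ParseError(f"video {s.video_id!r} missing from design table")
        groups.setdefault(str(label), []).append(s.log_mean_pairwise_distance)
        covs.setdefault(str(label), []).append(float(cov_of.get(s.video_id, np.nan)))
    cov_arrays = {k: np.array(v) for k, v in covs.items()}
    has_cov = all(np.isfinite(v).all() for v in cov_arrays.values())
    return GroupedObservations(
        groups={k: np.array(v) for k, v in groups.items()},
        covariate=cov_arrays if has_cov else None,
    )


__all__ = [
    "RunConfig",
    "config_hash",
    "read_tracks",
    "write_tracks",
    "tracks_to_frame",
    "summaries_to_frame",
    "write_summaries",
    "read_design",
    "write_null",
    "read_null",
    "run_pipeline",
    "grouped_from_summaries",
    "continuous_predictor_anova",
]
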