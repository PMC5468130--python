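"""Inferential layer: one-way ANOVA, Tukey HSD, and the null pseudo-group.

The response throughout is the natural-log mean pairwise distance, one value
per video.  The treatment comparison is a classical fixed-effects one-way
ANOVA computed from sums of squares, followed by all-pairs Tukey HSD using
the studentized range distribution (Tukey–Kramer for unequal group sizes).
Comparison against the random-dispersal model enters the simulated null's
per-video log means as an extra pseudo-group labelled "random", exactly as
one more treatment level.  A continuous predictor (e.g. population latitude
in decimal degrees) is tested by simple linear regression with an F test on
the slope, df (1, N-2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateCovariateError,
    DegenerateDataError,
    IncompatibilityError,
)
from .null import NullClassification, NullDistribution, classify_log_value

__all__ = [
    "GroupedObservations",
    "AnovaResult",
    "TukeyPair",
    "TukeyResult",
    "ComparisonResult",
    "one_way_anova",
    "tukey_hsd",
    "compare_with_null_group",
    "continuous_predictor_anova",
]


@dataclass
class GroupedObservations:
    """Per-video log mean pairwise distances, grouped by treatment label.

    ``covariate`` optionally maps each group label to an array of one
    continuous value per video (aligned with ``groups``), for regression
    designs such as latitude.
    """

    groups: dict[str, np.ndarray]
    covariate: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if not self.groups:
            raise DegenerateDataError("no groups supplied")
        for label, vals in self.groups.items():
            if vals.size == 0:
                raise DegenerateDataError(f"group {label!r} is empty")
            if not np.isfinite(vals).all():
                raise DegenerateDataError(f"group {label!r} contains non-finite values")
        if self.covariate is not None:
            self.covariate = {
                k: np.asarray(v, dtype=float) for k, v in self.covariate.items()
            }
            for label, vals in self.groups.items():
                cov = self.covariate.get(label)
                if cov is None or cov.shape != vals.shape:
                    raise DegenerateCovariateError(
                        f"group {label!r}: covariate missing or misaligned"
                    )

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    @property
    def n_total(self) -> int:
        return sum(v.size for v in self.groups.values())

    def pooled(self) -> np.ndarray:
        return np.concatenate(list(self.groups.values()))


@dataclass
class AnovaResult:
    """One-way (or regression) ANOVA table."""

    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    grand_mean: float
    SS_between: float
    SS_within: float
    infinite_F: bool = False  # zero within-group variance with unequal means


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    mean_difference: float  # mean(a) - mean(b)
    p_adjusted: float
    ci_lower: float
    ci_upper: float


@dataclass
class TukeyResult:
    """All-pairs Tukey HSD at family-wise error rate ``alpha``."""

    pairs: list[TukeyPair]
    alpha: float
    k_groups: int
    df_within: int

    def p_value(self, a: str, b: str) -> float:
        for pr in self.pairs:
            if {pr.group_a, pr.group_b} == {a, b}:
                return pr.p_adjusted
        raise KeyError(f"no pair ({a!r}, {b!r})")


@dataclass
class ComparisonResult:
    """Full inferential output for one design, including the null pseudo-group."""

    anova: AnovaResult
    tukey: TukeyResult
    classifications: dict[str, NullClassification]
    metadata: dict = field(default_factory=dict)


def _check_anova_input(obs: GroupedObservations) -> None:
    k = len(obs.groups)
    if k < 2:
        raise DegenerateDataError(f"ANOVA needs >= 2 groups, got {k}")
    if obs.n_total < k + 1:
        raise DegenerateDataError(
            f"ANOVA needs N >= k + 1 observations (N={obs.n_total}, k={k})"
        )


def one_way_anova(obs: GroupedObservations) -> AnovaResult:
    """Fixed-effects one-way ANOVA from sums of squares.

    F = (SS_between / (k-1)) / (SS_within / (N-k)); p from the upper tail of
    the F distribution.  Zero within-group variance with unequal group means
    is reported as F = inf, p = 0 with ``infinite_F`` set; fully constant
    data are a degenerate-data error.
    """
    _check_anova_input(obs)
    k = len(obs.groups)
    n_total = obs.n_total
    pooled = obs.pooled()
    grand = float(pooled.mean())

    ss_between = 0.0
    ss_within = 0.0
    means: dict[str, float] = {}
    for label, vals in obs.groups.items():
        m = float(vals.mean())
        means[label] = m
        ss_between += vals.size * (m - grand) ** 2
        ss_within += float(((vals - m) ** 2).sum())

    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            raise DegenerateDataError("all observations identical; ANOVA undefined")
        return AnovaResult(
            F=float("inf"), df_between=df_b, df_within=df_w, p=0.0,
            group_means=means, grand_mean=grand,
            SS_between=ss_between, SS_within=ss_within, infinite_F=True,
        )
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(
        F=float(F), df_between=df_b, df_within=df_w, p=p,
        group_means=means, grand_mean=grand,
        SS_between=float(ss_between), SS_within=float(ss_within),
    )


def tukey_hsd(obs: GroupedObservations, alpha: float = 0.05) -> TukeyResult:
    """All-pairs Tukey HSD via the studentized range distribution.

    For groups i, j: q = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)) — the
    Tukey–Kramer form, which reduces to classical Tukey when the design is
    balanced.  Adjusted p values and simultaneous CIs come from the
    studentized range with k groups and the ANOVA error df.
    """
    anova = one_way_anova(obs)
    if anova.infinite_F or anova.SS_within == 0.0:
        raise DegenerateDataError("zero within-group variance; Tukey HSD undefined")
    k = len(obs.groups)
    df_w = anova.df_within
    msw = anova.SS_within / df_w
    q_crit = float(stats.studentized_range.ppf(1.0 - alpha, k, df_w))

    labels = obs.labels
    pairs: list[TukeyPair] = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            na, nb = obs.groups[a].size, obs.groups[b].size
            diff = anova.group_means[a] - anova.group_means[b]
            se = np.sqrt(msw / 2.0 * (1.0 / na + 1.0 / nb))
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_w))
            half = q_crit * se
            pairs.append(
                TukeyPair(a, b, float(diff), min(max(p_adj, 0.0), 1.0),
                          float(diff - half), float(diff + half))
            )
    return TukeyResult(pairs=pairs, alpha=alpha, k_groups=k, df_within=df_w)


def compare_with_null_group(
    obs: GroupedObservations,
    null: NullDistribution,
    alpha: float = 0.05,
    null_label: str = "random",
) -> ComparisonResult:
    """Test observed groups against the CSR null as a Tukey pseudo-group.

    Appends the null's simulated per-video log means as one extra group,
    reruns ANOVA + Tukey over the enlarged design, and band-classifies each
    observed group's mean log distance against the null CI.
    """
    if not obs.groups:
        raise DegenerateDataError("no groups supplied")
    if null_label in obs.groups:
        raise IncompatibilityError(f"group label {null_label!r} already in use")
    augmented = GroupedObservations(
        groups={**obs.groups, null_label: null.log_video_means}
    )
    anova = one_way_anova(augmented)
    tukey = tukey_hsd(augmented, alpha=alpha)
    classifications = {
        label: classify_log_value(float(vals.mean()), null)
        for label, vals in obs.groups.items()
    }
    return ComparisonResult(
        anova=anova,
        tukey=tukey,
        classifications=classifications,
        metadata={
            "null_n_individuals": null.config.n_individuals,
            "null_n_videos": null.config.n_videos,
            "alpha": alpha,
        },
    )


def continuous_predictor_anova(obs: GroupedObservations) -> AnovaResult:
    """Regression F test of log mean distance on a continuous covariate.

    Simple least squares; F with df (1, N-2) tests slope = 0.  The fitted
    and residual sums of squares fill the ANOVA table's between/within slots.
    """
    if obs.covariate is None:
        raise DegenerateCovariateError("no covariate supplied")
    y = obs.pooled()
    x = np.concatenate([obs.covariate[label] for label in obs.labels])
    n = y.size
    if n < 3:
        raise DegenerateDataError(f"regression needs >= 3 videos, got {n}")
    if np.ptp(x) == 0.0:
        raise DegenerateCovariateError("covariate is constant")

    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_reg = float(((fitted - y.mean()) ** 2).sum())
    ss_res = float(((y - fitted) ** 2).sum())
    df_w = n - 2
    if ss_res == 0.0:
        return AnovaResult(
            F=float("inf"), df_between=1, df_within=df_w, p=0.0,
            group_means={"slope": float(slope), "intercept": float(intercept)},
            grand_mean=float(y.mean()), SS_between=ss_reg, SS_within=ss_res,
            infinite_F=True,
        )
    F = ss_reg / (ss_res / df_w)
    return AnovaResult(
        F=float(F), df_between=1, df_within=df_w,
        p=float(stats.f.sf(F, 1, df_w)),
        group_means={"slope": float(slope), "intercept": float(intercept)},
        grand_mean=float(y.mean()), SS_between=ss_reg, SS_within=ss_res,
    )
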