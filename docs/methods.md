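# Methods

## The assay statistic

A video is a time-ordered set of frames, each holding one (x, y) position
per individual in a circular arena (default diameter 14.5 cm; origin at the
centre; all geometry in cm). The pipeline applies three steps:

1. **Subsampling.** Raw frames are extracted every `raw_interval_s`
   (default 15 s; 360 frames in a 90-min video). Analysis keeps one frame
   per `analysis_interval_s` (default 180 s), starting at the first frame,
   giving 30 analysed frames. The subsampling phase is anchored at t = 0 so
   that 12 discarded frames correspond exactly to 2,160 s.
2. **Acclimation trim.** The first `acclimation_frames` analysed frames
   (default 12) are discarded: early positions reflect the experimenter's
   equidistant placement and handling agitation, not behaviour. 18 frames
   remain under defaults.
3. **Pooling.** All pairwise Euclidean distances from the retained frames
   are pooled and averaged; the natural log of that mean is the response
   used in every downstream test. Because each frame contributes the same
   number of pairs, the pooled mean equals the mean of per-frame means; the
   pooled form is canonical and frames with missing individuals are
   rejected by default (an explicit `allow_partial` mode drops — never
   imputes — incomplete frames, with a warning).

A pooled mean of exactly zero (all individuals coincident in every frame)
leaves the log undefined; the summary is returned flagged
(`log_defined=False`, NaN) rather than silently −∞.

Degenerate inputs are errors, not warnings: fewer than two individuals,
non-monotone timestamps, varying roster within a video, positions outside
the arena (with 1e-9 cm slack, since annotated points can sit on the dish
wall). Raw annotation exports in pixels are ingested via a scalar
`scale_cm_per_unit` calibrated from the known dish diameter.

## The CSR null model

The chance reference is complete spatial randomness: positions independent
and uniform over the disk **area** (radius drawn as r√U, not U·r). A null
"video" is `n_frames` (default 30) independent placements of the group;
`n_videos` (default 100) such videos yield an empirical distribution of
mean pairwise distances. Null videos are deliberately pushed through the
same `summarize_video` code path as observed data (with zero acclimation),
so the reference mimics the sampling procedure rather than re-implementing
it.

The 95% band is the percentile interval of the simulated video means,
computed with outward-rounded order statistics (`lower`/`higher` rounding)
so that at least the nominal fraction of the simulated means falls inside
the band by construction. Whether banding is done on the linear or log
scale is immaterial — ln is monotone — and classification is performed on
the log scale to mirror the test statistics: below the band is
*aggregative*, above is *overdispersed*, inside (inclusive) is *random*.

Sanity anchors: for two uniform points in a disk of radius r,
E[d] = 128r/(45π) ≈ 6.5645 cm at r = 7.25 cm, and by linearity of
expectation the grand mean is the same for every group size, while the band
narrows as group size grows (more pairs averaged per frame). The default
100-video band is the study-scale reference; calibration checks that need a
tight band use `n_videos=10,000`, because the fresh-draw coverage of a
percentile band built from only 100 samples is systematically below nominal
(≈93–94%) and has substantial band-to-band variance.

## Group comparisons

The response is always the log mean pairwise distance, one per video.
Group sizes are analysed separately — the maximum attainable pairwise
distance shrinks as more larvae share the dish, so sizes are not
comparable.

- **ANOVA.** Classical fixed-effects one-way ANOVA computed from sums of
  squares; F = (SS_between/(k−1))/(SS_within/(N−k)), upper-tail p. No Welch
  correction (homogeneous variances are assumed, matching the assay's
  original analysis); zero within-group variance with unequal means is
  reported as F = ∞, p = 0 with a flag.
- **Tukey HSD.** For each pair, q = |m_i − m_j| / √(MSW/2·(1/n_i + 1/n_j))
  — the Tukey–Kramer form, reducing to classical Tukey when balanced —
  with adjusted p from the studentized range (k groups, error df) and
  simultaneous CIs at family-wise α = 0.05 by default. p values are
  reported at full floating precision.
- **Null pseudo-group.** "Observed vs. chance" is implemented by appending
  the null's simulated per-video log means as one extra group labelled
  `random` and rerunning ANOVA + Tukey; all simulated videos enter (the
  pseudo-group size equals `n_videos`). A band classification of each
  observed group's mean is reported alongside, since the two views
  (hypothesis test and CI band) answer slightly different questions.
- **Continuous predictor.** Latitude-style predictors are tested by simple
  least-squares regression with an F test of slope = 0 on df (1, N−2).

## The synthetic-movement generator

The generator's only job is to produce tracks whose aggregation strength is
a known monotone function of one parameter; it is **not** a mechanistic
larva model. Individuals start equidistant on the dish rim (random global
rotation) and each 15-s step moves every individual by

    |N(step_cm, step_sd_cm)| · (random unit vector)
      + attraction · step_cm · (unit vector toward its neighbour target)

where the target is the centroid of neighbours within
`interaction_range_cm`, falling back to the nearest individual when none is
in range (so the rule degrades gracefully at n = 2). Overshoot past the
wall is folded back radially (specular in the radius), which preserves the
uniform equilibrium of the unbiased walk; absorbing or sliding walls would
distort that CSR limit.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `attraction` | 0 | pure random walk; ±1 are full-strength bias |
| `step_cm` | 0.5 cm / 15 s | order of a larval body length; a convention, not an estimate |
| `step_sd_cm` | 0.25 cm | mild step-length variability |
| `interaction_range_cm` | 10 cm | covers the initial perimeter spacing for n ≥ 3 (8.5 cm at n = 5) so strong attraction cannot stall in separate stable sub-clusters, yet stays local relative to the 14.5-cm dish |

What the generator emulates: perimeter starts, bounded arena, tunable
attraction from strong aggregation (+0.9 collapses groups to <1 cm mean
spacing) through neutral to active avoidance (−0.9 pushes pairs to
opposite walls). What it does **not** emulate: pheromone trails, feeding
sites, wall-following, circadian structure, realistic speeds or turning
kinematics. Passing tests therefore demonstrate that the *pipeline*
recovers known spatial structure, not that the movement model describes
real larvae.

One consequence worth knowing: at `step_cm = 0.5` the neutral
(attraction 0) walk mixes slowly, so the 18 retained frames — 12 raw steps
apart — are strongly autocorrelated and the per-video means of neutral
walks are over-dispersed relative to the CSR band (only ~a third of such
videos land inside it, even though their expectation matches the CSR
value). The CSR band is a reference for *independent* random placement,
not for any correlated random walk; calibration claims in the tests are
therefore made with CSR-generated videos, and the neutral walk is checked
via monotonicity and equilibrium location instead.

## Determinism and provenance

Every random component draws from a `numpy` Generator seeded explicitly;
experiment corpora spawn one child stream per video from a single
`SeedSequence`, so corpora are reproducible and order-independent. Every
output CSV begins with `# seed=...` and `# config=...` (a hash of all
analysis-relevant configuration), and writer/reader use 17-significant-
digit formatting with round-trip float parsing so coordinates survive a
write→read cycle bit-exactly.

## Problem sizes

Monte Carlo checks in the test suite and acceptance script use: 10,000
null videos for the closed-form oracle (n = 2), 2,000 per group size for
the size-invariance check, 1,000 replicates for band-coverage and ANOVA
type-I calibration, 10 replicate synthetic experiments for the
feeding/nonfeeding pattern, and 15 replicates per attraction level for the
monotonicity check. These sizes put Monte Carlo error comfortably below
the tolerances being asserted.

## Known limitations

- The CSR null ignores wall-following and other boundary artefacts; an
  animal that hugs the wall at random angular positions is *not* CSR and
  may classify as overdispersed.
- Classification compares a video (or group mean) to the band of simulated
  *means*; it is a descriptive label, not a hypothesis test — the Tukey
  pseudo-group comparison is the inferential counterpart.
- Only circular arenas and complete rosters are supported; there is no
  interpolation of missing positions.
- The movement model's attraction parameter is ordinal ground truth, not a
  biologically calibrated quantity.
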