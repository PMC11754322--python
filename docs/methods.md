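# Methods

This note documents the models and procedures implemented by
`explometrics`, the choices made where the design was genuinely open,
and what the synthetic validation does and does not demonstrate.

## Input model

A trajectory is an ordered sequence of planar positions $(x_i, y_i)$ in
virtual meters (vm), optionally timestamped, produced by logging an
agent moving at fixed speed through a bounded environment. All analysis
is strictly two-dimensional: loggers that record three axes are read by
mapping the two horizontal axes via `column_map`. One vm equals one
coordinate unit; no unit conversion is ever applied.

An environment supplies rectangular bounds, a square occupancy grid of
side `bin_size` anchored at `(xmin, ymin)` with half-open cells (the
grid origin is a package convention; bin assignment must be
deterministic and testable), an entropy normalization constant `k_norm`,
and landmark coordinates.

## Quality control and preprocessing

Because movement speed is fixed, step-length variability is a proxy for
sampling-rate variability, and isolated oversized steps indicate
logging lags. Per subject we report:

- the sampling rate, declared or recovered as `n_points / total_time`;
- the coefficient of variation (sd/mean) of nonzero step lengths
  (zero-length steps are pauses, not samples of movement speed);
- the lag fraction: share of steps longer than 3x the subject's median
  nonzero step (exclusion above 0.1%);
- movement time: nonzero steps divided by the sampling rate (exclusion
  below 30 s).

CoV outliers are flagged at the cohort level (CoV > Q3 + 3 IQR of the
cohort CoVs); with fewer than four subjects the screen is skipped.
Screens *flag* subjects rather than dropping them, so the effect of
each rule stays visible; the CLI applies the flags. CoV screening runs
on raw (pre-resampling) steps, since its motivation is detecting
sampling-rate variability.

Trajectories are then trimmed of leading idle samples (the last idle
position is retained so the first movement step is representable) and
resampled to a common 10 Hz grid by linear interpolation, using
timestamps when present and synthetic `i/rate` timestamps otherwise.

Two geometric resampling operations support the measures:

- **Constant-step rediscretization** (for sinuosity and the fractal
  dimension): walk the polyline and emit a point each time the distance
  from the previous emitted point reaches the step `q` (circle-path
  intersection, so emitted points lie on the original polyline and all
  emitted steps equal `q` to 1e-9).
- **Flight-scale simplification**: Ramer-Douglas-Peucker with
  perpendicular distance to the chord line, first maximal point kept on
  ties, endpoints always retained. Each retained segment is one flight
  (a run of steps with approximately constant heading).

## The fourteen measures

Extent of exploration: **path length** (sum of step lengths),
**pausing** (steps of length <= 1e-9, divided by the sampling rate; the
threshold is a numerical-zero convention since the source data carry no
explicit pause marker), **area covered** (distinct grid cells),
**roaming entropy** `RE = -sum p_i ln p_i / ln k`, with `p_i` the
per-sample occupancy share of cell i (occupancy is time-weighted on the
uniformly resampled grid, not per-entry) and `k` the normalization
constant, **minimum convex polygon** (convex hull area), and **landmark
visits** (distinct landmarks entered within a 20 vm radius).

Spatial shape: **fractal dimension** by the divider method — measure
the rediscretized path length `L(delta)` at 20 divider sizes
log-spaced from 0.5x to 10x the median nonzero step (the spacing is a
package choice; only the range and count are fixed by convention) and
take `D = 1 - slope` of `ln L` on `ln delta`, dropping divider sizes
the path cannot support (shorter than `2 delta`, or paths so confined
the walker never escapes radius `delta`); and **sinuosity**
`S = 1.18 sigma / sqrt(q)` where `sigma` is the standard deviation in
radians of the signed turning angles of the constant-step (`q`)
rediscretized path — the small-angle form for regular step lengths.

Efficiency: **revisiting** — place centers are chosen greedily along
the trajectory (the first sample is a center; any later sample farther
than 14 vm from all centers opens one), entries into each center's
disc are counted as for landmarks, and the measure is the mean of
(entries - 1) over centers. The greedy construction is one concrete,
deterministic reading of "returns to already visited places" and is
isolated behind a single function so it can be swapped. **Landmark
revisits** (total entries minus distinct landmarks; re-entry requires
fully exiting the 20 vm disc — no refractory time), **area efficiency**
(distinct cells / total cell entries) and **landmark efficiency**
(distinct landmarks / total entries, undefined and reported as missing
when a subject enters no landmark), **turnarounds** (step-scale turning
angles at 180 degrees, with 0.5 degrees of floating-point slack, pauses
skipped) and **flight turnarounds** (turning angles >= 160 degrees on
the RDP-simplified polyline at epsilon = 6 vm; the sub-180 cutoff
absorbs the heading jitter that keeps real reversals from hitting 180
exactly).

Parameter defaults (radius 20/14 vm, epsilon 6, cutoffs 160/180, bin
14 vm, 10 Hz, rediscretization step 0.48 vm — 15 vm and 0.50 in the
"silcton" profile) are the reference configuration for short
fixed-speed sessions in ~140 vm environments; all are exposed in
`MeasureParams`. When `rediscretize_step` is unset the pipeline uses
the pooled median nonzero step of the cohort.

Step-scale turnarounds are computed and exported but excluded from
clustering by default: small-scale strafing produces full-reversal
step angles that do not correspond to path retracing, while genuine
dead-end reversals rarely hit 180 degrees exactly at step scale — the
flight-scale variant is the reliable detector (the comb fixture makes
this contrast exact: five reversals, flight count 5, step count 0).

## Variable clustering

Measures are standardized (mean 0, sd 1, denominator n-1); subjects
with any missing measure are dropped with a logged count. Similarity
between variables is the squared Pearson correlation, so clustering is
blind to the direction of association. The homogeneity of a cluster is
the leading eigenvalue of the correlation matrix of its variables
(equivalently the sum of squared correlations with the cluster's first
principal component); agglomeration merges the pair minimizing
`d(A, B) = H(A) + H(B) - H(A u B)` and records `d` as the aggregation
height. For two singletons this closed form gives `1 - |r|`. Ties are
broken by the lexicographically smallest member name so trees are
platform-reproducible. Homogeneity is evaluated in closed form rather
than by iterative PC fitting: deterministic and exactly testable.

Cutting the tree at `k` undoes the last `n - k` merges. Each cluster's
synthetic variable is the first principal component of its standardized
members, scaled to unit variance and oriented so the mean correlation
with the members is positive (orientation is otherwise arbitrary);
loadings are Pearson correlations of every measure with every synthetic
variable. For display, efficiency-type measures (pausing, revisiting,
landmark revisits, flight turnarounds) can be negated via
`orient_measures` so higher always reads as more exploration or more
efficiency; the tree is invariant to this.

The number of clusters is suggested by an offline kneedle elbow on the
aggregation heights plotted against the number of clusters (heights
non-increasing, x = 1, 2, ...): min-max normalize, flip the
decreasing-convex curve to increasing-concave, and return the most
recent local maximum of the difference curve `y - x` once it drops
below the sensitivity-adjusted threshold (sensitivity 1 by default).
Exactly tied local maxima resolve to the latest one, per the published
procedure. The final `k` remains a user decision (CLI argument),
mirroring the usual combined visual-plus-kneedle practice.

## Synthetic cohorts

`synthdata` emulates fixed-speed sampled movement: a correlated random
walk at 10 Hz with step 0.48 vm in a bounded environment (default
140 x 140 vm, 14 vm bins, 20 landmarks), reflecting at the walls.
Per-sample behavior is governed by five latent traits: pause
probability (`activity`), wrapped-normal turning noise (`tortuosity`,
rad/sample), a dead-end turnaround rate, a pull toward the nearest
previously visited grid-cell center (`revisit_bias`) and a pull toward
the nearest unvisited landmark (`landmark_attraction`). Turning noise
is wrapped-normal (not von Mises) so the tortuosity trait corresponds
directly to the sigma in the sinuosity formula.

Dead-end turnarounds are executed as tight smooth U-turns (pi /
`uturn_steps` per sample; 18 samples by default, turn diameter about
5.5 vm) rather than instantaneous heading flips: a walking agent cannot
reverse within one 0.1 s sample, an instantaneous flip would inject a
large step-scale turning angle into the sinuosity statistic, and the
tight turn is still a full reversal at flight scale (diameter below the
6 vm simplification epsilon). U-turn initiation is drawn independently
of pausing so reversal counts track the turnaround trait rather than
the share of time spent moving.

The three-trait recovery study (`three_trait_sampler`) draws three
independent uniform latents and maps them to strongly separated trait
ranges: activity in [0, 0.75]; tortuosity in [0.06, 0.28] rad/sample
(persistence lengths of roughly 6-130 vm at 0.48 vm steps — the upper
end is visibly tortuous without collapsing area coverage, which would
bleed the shape trait into the extent measures); and an inefficiency
latent driving both the turnaround rate (up to 0.012/sample) and the
revisit pull (weight up to 0.05 — deliberately small, because a strong
continuous pull corrupts per-step heading statistics and would load
the shape measures on the wrong trait). Landmark attraction is off so
landmark measures stay outside the trait structure.

What the simulator does *not* emulate: walls and path networks inside
the environment (layout landmarks are attractors, not constraints),
goal-directed search instructions, sampling-rate jitter or logging
lags (these are injected explicitly in the QC tests), and any claim of
human behavioral realism. Recovery of the three measure blocks —
{path length, pausing, area covered, roaming entropy} /
{sinuosity, fractal dimension} /
{revisiting, area efficiency, flight turnarounds} — at k = 3 in >= 90%
of 20 replicates of 200 agents therefore shows that the pipeline
separates measures driven by distinct behavioral axes under realistic
noise; it does not by itself establish the component structure of real
human cohorts.

## Numerical choices and degenerate inputs

- Roaming entropy uses natural logarithms throughout (the base cancels
  in the ratio).
- Collinear point sets have hull area 0 (reported, not an error).
- The divider-method fit requires at least 3 usable divider sizes;
  fewer is an error, as is a path shorter than one rediscretization
  step.
- A subject with no movement at all yields a QC report with
  `movement_seconds = 0` and reason `no_movement` rather than an
  exception; an all-idle trajectory cannot be trimmed and is a
  degenerate-input error.
- Points outside the environment bounds are clamped to the border cell
  and counted (clamping is logged); out-of-bounds exclusion belongs to
  QC, not binning.
- RDP keeps the first maximal point on ties; merge ties in clustering
  break lexicographically.
- Three inner loops (the rediscretizer, greedy place centers, and the
  walker) are JIT-compiled with numba when available; pure-Python twins
  with identical arithmetic are the fallback.

## Problem sizes

The validation suite uses cohorts of 200 agents at 150 s x 10 Hz for
the recovery study (20 replicates), 50-agent arms for the monotone
trait-measure link checks at 60-150 s, and 100 random instances for
each geometry oracle check; these sizes give stable correlation
structure (sampling error on r of about 0.07 at n = 200) while keeping
a full run in the low minutes on one core.

## Known limitations

- The greedy revisiting construction depends on trajectory direction:
  reversing a trajectory can change the place centers. It is
  deterministic and documented, but not canonical.
- `landmark_efficiency` is undefined for subjects who visit no
  landmark; downstream clustering drops such subjects, which can bias
  a cohort toward more active explorers.
- The kneedle suggestion is advisory; on curves without a clear elbow
  it returns nothing and the CLI falls back to k = 3.
- Reflection at walls preserves step length except when a step is
  folded at a corner; wall-hugging agents can therefore show a small
  nonzero step-length CoV, which the cohort screen may flag when the
  cohort CoV spread is otherwise degenerate (near-zero IQR).
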