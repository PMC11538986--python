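# Methods

This note documents the models and procedures implemented in `nightshare`,
the parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Data model

All analysis runs in planar metres. Geographic input (lon/lat) is projected
with a local tangent-plane (equirectangular) projection centred on the data;
over a study area of a few tens of kilometres the distortion is well under a
metre, which is far below collar error. Timestamps are timezone-aware and all
time-of-day windows (night 20:00–04:00, sleep period 21:00–05:00, day window
08:30–17:30) are local clock times.

Trajectories live on a strictly regular 15-min grid anchored at local
midnight and shared across individuals, so dyadic comparisons never need
alignment logic. Each grid point carries a provenance flag
(observed / interpolated / corrected / missing).

## Preprocessing

- **Regularization.** Fixes snap to the nearest grid slot within half an
  interval; interior gaps of ≤4 intervals (1 h) are linearly interpolated,
  longer gaps stay missing. Four intervals is short enough that linear
  interpolation cannot invent biologically implausible paths at baboon
  travel speeds.
- **Anomaly repair.** A point is a spike when the displacements to and from
  it both imply >3 m/s sustained over an interval while its neighbours are
  mutually reachable below that speed (an out-and-back pattern). Spikes are
  replaced by the neighbour midpoint. The out-and-back form was chosen over
  a pure speed filter so genuine flight responses (fast but one-directional)
  survive.
- **Jitter removal.** Within the night window, points within 20 m of the
  night's median location snap to that median; 20 m is a typical stationary
  collar error. Daytime points are never altered.
- **Group tracks.** Where several collared members of one group have
  simultaneous data, the member with the longest total data duration
  represents the group (group-level duplicates removed in its favour).

## Sleeping sites

Nightly centroids are means of the night-window fixes (≥8 of 32 possible
fixes required; sparser nights are skipped). Centroids are clustered by
complete-linkage agglomerative clustering on Euclidean distance, cut at
500 m. Complete linkage bounds the within-site diameter by the cut height;
with sites kilometres apart and night spreads of metres, any cut between
~100 m and ~3 km yields the same partition, so the exact value is not
delicate. A night is *shared* when ≥2 distinct groups are assigned the same
site on the same night.

## Home ranges

The utilization distribution is a Gaussian-kernel density estimate evaluated
on a 50-m grid padded three bandwidths beyond the data, stored as
cell-integrated mass. The bandwidth defaults to the reference (Scott) rule
with a scalar override. The L% home range is the smallest set of
highest-density cells reaching L of the mass (area = cell count × cell
area); overlap is reported as directed area proportions and as
Bhattacharyya's affinity Σ√(p₁p₂), computed on a common grid (the finer of
the two, with mass-preserving rebinning) when grids differ.

## Day-shift permutation engine

The null model for all intergroup questions rotates one track of a dyad by a
uniformly random whole number of days (1 … n−1, sampled without replacement
across replicates when possible; a full rotation is disallowed). Rotation
preserves each track's marginal space use exactly (multiset of
time-of-day × location) and all within-day structure, destroying only the
concurrency between the two tracks.

Day blocks are anchored at **local noon**, not midnight. A night
(20:00–04:00) spans midnight, so midnight-anchored rotation would splice the
seam night from two different evenings; with noon anchoring every night
stays intact and the single seam falls in the middle of a day. This matters
most for the sleeping-site-choice null, where each replicate re-derives the
shifted group's nightly site assignments from its shifted coordinates: with
intact nights the replicate assignment sequence is an exact rotation of the
empirical one.

Following the study convention, a result is *significant* when the empirical
value falls outside the 90% inter-quantile band of the null distribution.
One-sided permutation p-values with the add-one correction, (1+k)/(n+1), are
reported in both directions; they lie in [1/(n+1), 1] by construction. For
strongly discrete statistics (the sharing proportion) quantile ties make the
band test conservative — calibration experiments show non-rejection rates
above the nominal 90% rather than at it.

The site-specific post-sharing null conditions on permuted sharing of one
particular site and evaluates the next day's movement metrics; with fewer
than 20 permuted sharing instances it *abstains* rather than reporting an
unreliable p-value.

## Response radius

Dyad timestamps are pooled into 100-m bins of intergroup distance and the
mean heading difference per bin is compared with the day-shift null's 5th
and 95th percentiles. Three estimator choices were made here, all exposed in
`AnalysisConfig`:

1. **Minimum step 25 m** for a defined heading. Displacements at or below
   collar-noise scale produce uniformly random headings; with the nominal
   1-m threshold the 0–100 m bin is dominated by stationary-noise headings
   from animals sitting at (possibly shared) sites around the day-window
   edges, which masks any real coordination there.
2. **Foraging-window pooling (08:30–14:30).** During the return-to-roost leg
   travel is destination-driven: groups returning to the same refuge
   converge and groups bound for different refuges diverge, regardless of
   any social response. Both effects mimic (anti)coordination at arbitrary
   distances and are exactly the environmental forcing the site-specific
   null exists to control; excluding the return leg removes them from the
   radius estimate. The same window is used for the post-sharing next-day
   metrics.
3. **Decision-time binning.** The displacement arriving at time t is a
   response to the separation at t−1, so each heading-difference value is
   binned by the previous slot's distance. Binning by concurrent distance
   smears coupled "exit steps" into bins beyond the true radius and biases
   recovery upward by one to several bins.

The radius is the upper edge of the contiguous run of bins, ascending from
zero, whose empirical value lies outside the band; a bin inside the band —
or one with fewer than 50 observations, which carries no evidence of
coordination — ends the scan. With no near-range signal the radius is 0.

## Interactions

Interactions are maximal day-window runs of timestamps within the response
radius; runs separated by less than 75 min merge; runs never span a night
(continuous overnight proximity counts as one interaction per day). A dyad
moves *cohesively* when some contiguous run keeps it within the 80% quantile
of daytime within-group dyadic distances while either group travels ≥100 m.
The front/behind score at step t is d(b_t, c_{t+1}) − d(a_t, c_{t+1}) with c
the dyad centroid — positive when the first group leads; it negates exactly
under dyad swap.

## Sleep

Each one-minute tri-axial burst (nominally 32 samples at 10.54 Hz) reduces
to its mean gravity vector; the posture angle is that vector's elevation.
A minute is *sleep* when inside a run of ≥5 consecutive minutes whose
successive absolute angle changes all stay below 5° — sustained postural
stability — and *wake* otherwise; minutes without a burst are missing, and
all-zero (dead-sensor) bursts become missing. The (5°, 5 min) defaults are
exposed; total sleep time is monotone in the angle threshold.

Nightly metrics over 21:00–05:00 (nights with <50% of the period classified
are unusable): TST = sleep minutes; efficiency = TST / classified minutes;
fragmentation = wake bouts ≥2 min per hour of sleep (undefined, not
infinite, when TST = 0; missing minutes break bouts); onset/offset = bounds
of the first/last ≥5-min sleep run inside a 19:00–07:00 search window.
Synchronization is the agreement fraction over jointly classified
sleep-period minutes of a cross-group pair.

The sharing → sleep contrast is reported descriptively: difference in means
(shared − unshared nights) with 95% percentile CIs from an individual-level
block bootstrap (whole individuals resampled), which respects the
repeated-measures structure. Hierarchical regression modelling of these
tables is deliberately out of scope; the effect tables carry the group /
individual / date / site identifiers such models need.

## Synthetic data generator

The generator emulates the structure of a multi-group collar study on a
savannah landscape:

- **Sites**: 24 sites on a jittered grid with ≥3 km minimum spacing
  (real inter-site distances are of order 6 km). Each group draws nightly
  from a repertoire of its ~10 nearest sites (with a fix-up guaranteeing
  every site is in someone's repertoire); with probability `p_share` a
  random dyad is forced to a common site. Under *independent* choice,
  chance collisions also produce shared nights at a few percent of nights —
  matching the observed study-system rate — while *exclusive* choice
  resamples collisions for experiments that need sharing fully switched
  off.
- **Movement**: an Ornstein-Uhlenbeck-anchored correlated random walk.
  Nights sit at the site ± 5 m jitter; days run 08:30–17:30 with a
  ~140 m/15-min step scale (≈5 km daily travel), heading persistence, a
  pull toward a day-specific foraging anchor (home centre ± 500 m — groups
  do not forage at the same spot every day), and a ramped pull to the
  night's site over the last three hours. Within-group individuals ride the
  group path plus a slow OU offset with ~25 m stationary spread, giving a
  mean within-group dyadic distance near the observed ~44 m.
- **Attraction**: on attraction-active dyad-days (a configurable window
  after a shared night, or always, or never) and only within the true
  response radius, the dyad's *realized* displacement directions are
  aligned (80% weight toward the common direction, 0.2 rad scatter) with a
  capped mutual pull; days that begin together also share a foraging
  anchor (joint foraging). The internal heading state stays independent of
  coupling, so alignment vanishes as soon as a dyad separates beyond the
  radius — without this, residual alignment leaks into bins beyond the true
  radius.
- **Sleep**: within a night (onset ≈19:30, offset ≈06:00, ±10 min) sleep
  and wake bouts alternate with exponential durations (means 25 and
  3.5 min, giving ~84% efficiency and ~1.7 awakenings/h, near the observed
  values). On shared nights the wake-bout initiation rate is ×1.5, with the
  extra initiations drawn as *site-level common events* (same minute and
  duration for every individual at the site): sharing then shortens and
  fragments sleep while increasing cross-group synchronization, as
  disturbances at a common refuge should.
- **Accelerometry**: sleep minutes keep a per-bout orientation with 0.8°
  angle jitter and 0.02 g sample noise; wake minutes re-draw orientation
  uniformly with 0.25 g noise.

Scenario presets pin the validation experiments: `null_independent` (2
groups, 120 days, everything off), `attraction_after_sharing` (sharing at an
elevated 15%/night so that ~20 attraction episodes occur in 120 days — at
the field rate of ~3% a desk-scale simulation would contain too few events
to test against), `radius_600` (200 days, overlapping ranges, coupling
always on inside 600 m, chosen so every 100-m bin below the radius exceeds
the 50-observation evidence floor), and `sleep_disruption` (the study-like
4-group / 6-individual layout with 25% sharing).

**What the generator does not emulate** — and hence what passing tests do
not show about field data: terrain and landscape anisotropy, collar fix
failure and habitat-dependent error, seasonal home-range drift, demography,
predators, more than two collared individuals per group, and sub-15-min
herding dynamics. Calibration results transfer only insofar as real
movement is approximately stationary at the day scale, which is also the
assumption of the day-shift null itself.

## Numerical notes

- KDE accuracy: against an analytic Gaussian the UD's L1 error is ~0.05 at
  n = 20 000 points (reference-rule bandwidth); the error floor at n = 5000
  is ~0.07, set by estimator variance, not grid resolution.
- Permutation reproducibility: every stochastic routine takes a seed;
  identical seeds give bitwise-identical outputs (tested).
- Offsets are sampled with replacement (with a warning) when fewer distinct
  day offsets exist than requested permutations.
- Degenerate inputs: single-point tracks, all-identical UD inputs, empty
  within-group dyad pools, zero-sleep nights and all-sparse radius bins all
  raise explicit errors or produce flagged missing values rather than NaNs
  propagating silently.

## Known limitations

- The response-radius estimator assumes the coordination signal is
  expressed in headings; a pluggable metric (step-length difference) is
  provided but the default was validated mainly on heading coupling.
- The sharing-proportion band test is conservative for short studies
  because the statistic is lattice-valued.
- Bootstrap CIs with very few individuals (≤3) are coarse; the effect
  tables are the intended input to hierarchical models when more structure
  is needed.
- The simulator's two-state sleep process has no circadian depth structure
  within the night; classifier accuracy on real accelerometry will be lower
  than on synthetic nights (the study system reports ~80% against video).
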