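# nightshare

Night/day analysis of GPS-tracked animal groups: where they sleep, when they
share a sleeping site, how sharing reshapes daytime intergroup relationships,
and what it costs in sleep.

Wild group-living animals — the motivating system is olive baboon groups
tracked with GPS/accelerometer collars — spend their nights at a small number
of discrete refuges (cliffs, tree groves). When two groups end up at the same
refuge, the encounter may carry over into the next day as spatial attraction
and coordinated travel, and may degrade that night's sleep. `nightshare`
implements the full analysis chain for this question, plus a synthetic
multi-group movement and accelerometry simulator with known ground truth, so
every stage can be validated end to end without field data.

## What it computes

- **Preprocessing** — snap 15-min GPS fixes to a common grid, interpolate
  short gaps, repair out-and-back spikes, remove night-time jitter, and build
  one representative track per group.
- **Sleeping sites** — nightly centroids (mean of fixes 20:00–04:00),
  complete-linkage agglomerative clustering cut at a fixed height (500 m),
  per-night site assignments, and "shared" flags when ≥2 groups use the same
  site on the same night.
- **Home ranges** — kernel-density utilization distributions (UD), the 95%
  home range, directed overlap, and Bhattacharyya's affinity
  `BA = Σ √(p₁p₂) ∈ [0, 1]`.
- **Response radius** — the intergroup distance below which movement is
  statistically coordinated: pool dyad timestamps into 100-m distance bins,
  compare each bin's mean heading difference against day-shift null
  percentiles, and report the upper edge of the contiguous run of
  outside-the-band bins ascending from zero.
- **Interactions** — maximal day-window (08:30–17:30) runs within the
  response radius, merged across gaps < 75 min, never spanning a night;
  cohesive-movement classification (≥100 m of joint travel while within the
  80% quantile of within-group dyadic distances); front/behind scores
  relative to the dyad's direction of travel.
- **Permutation nulls** — the day-shift engine rotates one track of a dyad by
  whole days (noon-anchored blocks keep every night intact), preserving each
  track's space use and daily structure while destroying concurrency. Three
  null models: (1) attraction/avoidance on five dyadic metrics (mean
  distance, association time, and within-radius distance / heading
  difference / step-length difference); (2) sleeping-site choice (shared
  proportion of co-tracked nights, assignments re-derived per replicate);
  (3) site-specific next-day movement after sharing, which abstains below 20
  permuted sharing instances. Significance = empirical value outside the 90%
  inter-quantile null band; one-sided permutation p-values
  `(1+k)/(n+1)` are reported in both directions.
- **Sleep** — per-minute posture angles from tri-axial burst means
  (`atan2(az, √(ax²+ay²))`); a minute is *sleep* when inside a run of ≥5
  minutes whose successive angle changes stay below 5°. Nightly metrics over
  21:00–05:00: total sleep time (TST), efficiency, fragmentation (wake bouts
  ≥2 min per hour of sleep), onset/offset, dyadic sleep/wake synchronization,
  model-ready effect tables, and individual-block bootstrap contrasts for
  shared vs unshared nights.

## Worked example

```python
from nightshare import AnalysisConfig, make_scenario, simulate_gps, run_pipeline, report
from nightshare.simulate import simulate_sleep_labels, simulate_accel_frame

cfg, _ = make_scenario("attraction_after_sharing", seed=2, n_days=40)
gps, truth = simulate_gps(cfg)
accel = simulate_accel_frame(simulate_sleep_labels(truth, cfg), cfg)
out = run_pipeline(gps, accel, AnalysisConfig(), "runs/demo", seed=1, n_perm=50)
print(report(out))
```

prints (abridged):

```
Permutation null models (empirical vs 90% null band):
  G1-G2        mean_distance          emp=7.21e+03 band=[7.11e+03, 8.28e+03] p_low=0.098 p_high=0.922
  G1-G2        assoc_time             emp=0.225 band=[0.014, 0.0633] p_low=1 p_high=0.0196 *
  G1-G2        heading_diff           emp=28.2 band=[51.1, 92.4] p_low=0.0196 p_high=1 *
  G1-G2        sharing                emp=0.268 band=[0, 0.0732] p_low=1 p_high=0.0196 *
  G1-G2        post_sharing:C11       emp=272 band=[456, 1.39e+03] p_low=0.0588 p_high=1 *
  G1-G2        post_sharing:C12       ABSTAINED (instances=7)

Interactions: 19 total; 11 on days after a shared night; 5 cohesive.

Sleep contrasts (shared - unshared nights, 95% bootstrap CI):
  total_sleep_time_min   -18.883 [-26.700, -11.067]
  sleep_efficiency       -0.039 [-0.056, -0.023]
  fragmentation          +0.484 [+0.417, +0.550]
```

Read: the two simulated groups associate far more (`assoc_time` 22.5% of
timestamps within the radius vs ≤6.3% by chance) and align headings within
the radius (28° vs ≥51° by chance); they share sleeping sites on 26.8% of
nights in this high-sharing scenario; on days after sharing site `C11` they
stay markedly closer (272 m) than the site-specific null allows; and
site-specific nulls with too few permuted sharing instances abstain instead
of reporting a p-value. The sleep contrasts recover the simulated
disturbance: shorter, less efficient and more fragmented sleep on shared
nights. (At this short 40-day scale the distance-bin counts are too sparse
to infer a response radius, so interactions fall back to the default 600 m.)

The same stages are available as a CLI: `nightshare simulate|run|report|
sites|radius|permtest` (see `nightshare --help`).

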