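"""Dyadic intergroup interactions and the empirical response radius.

The response radius is the intergroup distance below which movement becomes
statistically coordinated: dyad timestamps are pooled into 100-m distance
bins, a coordination metric (mean heading difference by default) is computed
per bin, and compared with per-bin day-shift null percentiles.  The radius
is the lower edge of the first bin, ascending from zero, whose empirical
value lies inside the null band.

Interactions are maximal day-window runs of timestamps within the radius,
with runs less than 75 min apart merged; an interaction never spans a night
(overnight continuity counts as one interaction per day).  A dyad moves
"cohesively" when it travels at least 100 m while staying within the
typical within-group spread (the 80% quantile of daytime distances between
collared group mates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig, in_window
from .io import get_logger
from .permutation import (_headings_steps, aligned_day_blocks, circular_diff_deg,
                          random_offsets)
from .preprocess import Trajectory

__all__ = ["DyadSeries", "Interaction", "ResponseRadiusResult", "dyad_series",
           "infer_response_radius", "extract_interactions",
           "within_group_threshold", "classify_cohesion", "front_behind_scores"]

log = get_logger()


@dataclass
class DyadSeries:
    """Per-timestamp distance and movement comparison for one group pair."""

    group_a: str
    group_b: str
    times: pd.DatetimeIndex
    xy_a: np.ndarray
    xy_b: np.ndarray
    distance: np.ndarray
    heading_a: np.ndarray      # degrees, NaN when step < min_step
    heading_b: np.ndarray
    heading_diff: np.ndarray   # circular, [0, 180]
    step_a: np.ndarray
    step_b: np.ndarray
    step_diff: np.ndarray

    def __len__(self):
        return len(self.times)


@dataclass
class Interaction:
    group_a: str
    group_b: str
    start: pd.Timestamp
    end: pd.Timestamp
    duration_h: float
    slots: np.ndarray = field(repr=False)          # indices into the dyad series
    cohesive: bool | None = None
    preceded_by_shared_night: bool = False
    front_behind_mean: float = np.nan


@dataclass
class ResponseRadiusResult:
    bin_edges: np.ndarray          # ascending from 0, width radius_bin_m
    empirical: np.ndarray          # metric per bin (NaN where empty)
    counts: np.ndarray             # pooled observations per bin
    null_lo: np.ndarray            # 5th null percentile per bin
    null_hi: np.ndarray            # 95th
    radius_m: float
    metric: str
    n_perm: int


def dyad_series(track_a: Trajectory, track_b: Trajectory,
                min_step_m: float = 1.0) -> DyadSeries:
    """Distance / heading / step comparison on the tracks' common grid."""
    if track_a.interval != track_b.interval:
        raise ValueError("tracks must share a sampling interval")
    start = max(track_a.start, track_b.start)
    end = min(track_a.times[-1], track_b.times[-1])
    if start > end:
        log.warning("dyad_series: disjoint coverage for %s-%s",
                    track_a.group_id, track_b.group_id)
        empty = np.empty(0)
        return DyadSeries(track_a.group_id, track_b.group_id,
                          pd.DatetimeIndex([], tz=track_a.start.tz), *( [np.empty((0, 2))] * 2), *( [empty] * 7))
    def cut(t):
        j0 = int((start - t.start) / t.interval)
        n = int((end - start) / t.interval) + 1
        return t.xy[j0: j0 + n]
    xa, xb = cut(track_a), cut(track_b)
    times = pd.date_range(start, end, freq=track_a.interval)
    dist = np.hypot(*(xa - xb).T)
    ha, sa = _headings_steps(xa, min_step_m)
    hb, sb = _headings_steps(xb, min_step_m)
    return DyadSeries(track_a.group_id, track_b.group_id, times, xa, xb, dist,
                      ha, hb, circular_diff_deg(ha, hb), sa, sb, np.abs(sa - sb))


# ---------------------------------------------------------------------------
# response radius

def _binned_metric(dist, metric_vals, edges):
    """Per-bin mean of metric_vals and per-bin counts (NaN-aware)."""
    ok = np.isfinite(dist) & np.isfinite(metric_vals) & (dist < edges[-1])
    idx = np.clip((dist[ok] / (edges[1] - edges[0])).astype(int), 0, len(edges) - 2)
    nb = len(edges) - 1
    cnt = np.bincount(idx, minlength=nb).astype(float)
    tot = np.bincount(idx, weights=metric_vals[ok], minlength=nb)
    with np.errstate(invalid="ignore"):
        return tot / np.where(cnt > 0, cnt, np.nan), cnt


def infer_response_radius(dyad_tracks, config: AnalysisConfig | None = None,
                          metric: str = "heading_diff", n_perm: int | None = None,
                          seed: int = 0) -> ResponseRadiusResult:
    """Infer the response radius from one or more dyads of group tracks.

    ``dyad_tracks`` is a list of (track_a, track_b) pairs; timestamps are
    pooled across dyads per distance bin.  The coordination metric is
    ``heading_diff`` (default), ``step_diff`` or ``distance_defined`` and is
    recomputed for every day-shift replicate against the permuted concurrent
    distances.  Bins with fewer than ``config.radius_min_obs`` empirical
    observations carry no evidence and are treated as consistent with the
    null.
    """
    config = config or AnalysisConfig()
    n_perm = n_perm or config.n_permutations
    rng = np.random.default_rng(seed)
    edges = np.arange(0, config.radius_max_m + config.radius_bin_m,
                      config.radius_bin_m)
    nb_bins = len(edges) - 1

    def metric_series(xa, xb):
        if metric == "heading_diff":
            ha, _ = _headings_steps(xa, config.min_step_m)
            hb, _ = _headings_steps(xb, config.min_step_m)
            return circular_diff_deg(ha, hb)
        if metric == "step_diff":
            _, sa = _headings_steps(xa, config.min_step_m)
            _, sb = _headings_steps(xb, config.min_step_m)
            return np.abs(sa - sb)
        raise KeyError(f"unknown radius metric {metric!r}")

    emp_tot = np.zeros(nb_bins)
    emp_cnt = np.zeros(nb_bins)
    null_tot = np.zeros((n_perm, nb_bins))
    null_cnt = np.zeros((n_perm, nb_bins))
    used = 0
    for ta, tb in dyad_tracks:
        ab = aligned_day_blocks(ta, tb, config.day_start_hour)
        if ab is None:
            continue
        used += 1
        A, B, times = ab
        nb_days = A.shape[0]
        # Pool only day-window timestamps: interactions are defined between
        # departure and return, and night fixes sit at sites where headings
        # reflect collar noise, not travel.  The displacement arriving at t
        # is a response to the separation at t-1, so each metric value is
        # binned by the decision-time distance.
        day = in_window(times, config.foraging_window, closed="both")[1:]
        xa, xb = A.reshape(-1, 2), B.reshape(-1, 2)

        def binned(xbv):
            d_lag = np.hypot(*(xa[:-1] - xbv[:-1]).T)
            mv = metric_series(xa, xbv)[1:]
            return _binned_metric(d_lag[day], mv[day], edges)

        m, c = binned(xb)
        emp_tot += np.where(c > 0, m * c, 0.0)
        emp_cnt += c
        offs = random_offsets(nb_days, n_perm, rng)
        for i, k in enumerate(offs):
            m, c = binned(np.roll(B, k, axis=0).reshape(-1, 2))
            null_tot[i] += np.where(c > 0, m * c, 0.0)
            null_cnt[i] += c
    if used == 0:
        raise ValueError("no dyad had usable overlapping data")
    with np.errstate(invalid="ignore"):
        empirical = emp_tot / np.where(emp_cnt > 0, emp_cnt, np.nan)
        null_bins = null_tot / np.where(null_cnt > 0, null_cnt, np.nan)
    null_lo = np.nanpercentile(null_bins, 100 * config.null_band[0], axis=0)
    null_hi = np.nanpercentile(null_bins, 100 * config.null_band[1], axis=0)

    if not (emp_cnt >= config.radius_min_obs).any():
        raise ValueError("all distance bins below the minimum observation count")
    # ascend from zero: the radius is the upper edge of the contiguous prefix
    # of bins whose empirical value falls outside the null band; a bin inside
    # the band — or one too sparse to carry evidence of coordination — ends
    # the scan, so with no near-range signal the radius is 0
    radius = 0.0
    for b in range(nb_bins):
        sparse = emp_cnt[b] < config.radius_min_obs or not np.isfinite(empirical[b])
        inside = (not sparse and np.isfinite(null_lo[b])
                  and null_lo[b] <= empirical[b] <= null_hi[b])
        if sparse or inside:
            break
        radius = float(edges[b + 1])
    return ResponseRadiusResult(edges, empirical, emp_cnt, null_lo, null_hi,
                                radius, metric, n_perm)


# ---------------------------------------------------------------------------
# interaction extraction

def _merge_runs(runs: list[tuple[int, int]], gap_slots: float):
    """Merge [start, end] index runs whose separation (next start minus
    previous end) is strictly below the limit."""
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap_slots:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def extract_interactions(ds: DyadSeries, radius_m: float,
                         config: AnalysisConfig | None = None,
                         shared_night_table: pd.DataFrame | None = None) -> list[Interaction]:
    """Maximal within-radius day-window runs, merged across short gaps.

    Runs separated by less than ``merge_gap_min`` are one interaction; runs
    never span a night boundary, so overnight continuity yields one
    interaction per day.  ``shared_night_table`` (columns group_a, group_b,
    night_date, same_site) sets ``preceded_by_shared_night``.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    config = config or AnalysisConfig()
    gap_slots = config.merge_gap_min / config.sampling_interval_min
    day = in_window(ds.times, config.day_window, closed="both")
    within = day & np.isfinite(ds.distance) & (ds.distance <= radius_m)

    shared_dates = set()
    if shared_night_table is not None and len(shared_night_table):
        t = shared_night_table
        sel = t[((t["group_a"] == ds.group_a) & (t["group_b"] == ds.group_b) |
                 (t["group_a"] == ds.group_b) & (t["group_b"] == ds.group_a))
                & t["same_site"].astype(bool)]
        shared_dates = {pd.Timestamp(d).date() for d in sel["night_date"]}

    out = []
    dates = ds.times.normalize()
    for d in dates.unique():
        sel = np.flatnonzero((dates == d) & within)
        if len(sel) == 0:
            continue
        breaks = np.flatnonzero(np.diff(sel) > 1) + 1
        runs = [(int(r[0]), int(r[-1])) for r in np.split(sel, breaks)]
        for s, e in _merge_runs(runs, gap_slots):
            slots = np.arange(s, e + 1)
            dur = (ds.times[e] - ds.times[s] + config.interval).total_seconds() / 3600
            out.append(Interaction(
                ds.group_a, ds.group_b, ds.times[s], ds.times[e], dur, slots,
                preceded_by_shared_night=(d - pd.Timedelta(days=1)).date() in shared_dates))
    return out


def within_group_threshold(member_trajectories: list[Trajectory],
                           quantile: float = 0.80,
                           day_window=("08:30", "17:30")) -> float:
    """Quantile of pooled daytime distances between collared group mates."""
    from itertools import combinations
    pool = []
    by_group: dict[str, list[Trajectory]] = {}
    for t in member_trajectories:
        by_group.setdefault(t.group_id, []).append(t)
    for members in by_group.values():
        for ta, tb in combinations(members, 2):
            ds = dyad_series(ta, tb)
            if len(ds) == 0:
                continue
            day = in_window(ds.times, day_window, closed="both")
            d = ds.distance[day]
            pool.append(d[np.isfinite(d)])
    pool = np.concatenate(pool) if pool else np.empty(0)
    if len(pool) == 0:
        raise ValueError(
            "no same-group collared dyads with simultaneous daytime data; "
            "configure an explicit cohesion threshold instead")
    return float(np.quantile(pool, quantile))


def classify_cohesion(interaction: Interaction, ds: DyadSeries,
                      threshold_m: float, min_travel_m: float = 100.0) -> bool:
    """Cohesive iff some contiguous run within the interaction keeps the
    dyad within ``threshold_m`` throughout while either group's path length
    over the run reaches ``min_travel_m``."""
    slots = interaction.slots
    close = np.isfinite(ds.distance[slots]) & (ds.distance[slots] <= threshold_m)
    # maximal runs of `close`, broken at merged-gap slot discontinuities
    runs, start = [], None
    for i in range(len(slots)):
        discont = i > 0 and slots[i] != slots[i - 1] + 1
        if close[i] and not discont and start is not None:
            continue
        if start is not None:
            runs.append((start, i - 1))
            start = None
        if close[i]:
            start = i
    if start is not None:
        runs.append((start, len(slots) - 1))
    for s, e in runs:
        if e <= s:
            continue
        idx = slots[s: e + 1]
        for xy in (ds.xy_a, ds.xy_b):
            steps = np.linalg.norm(np.diff(xy[idx], axis=0), axis=1)
            if np.nansum(steps) >= min_travel_m:
                return True
    return False


def front_behind_scores(ds: DyadSeries, slots: np.ndarray | None = None):
    """Travel-direction positioning scores.

    score(t) = dist(b_t, c_{t+1}) - dist(a_t, c_{t+1}) with c the dyad
    centroid; positive means group_a is in front.  Returns (scores, mean).
    """
    if slots is None:
        slots = np.arange(len(ds) - 1)
    slots = np.asarray(slots)
    slots = slots[slots + 1 < len(ds)]
    c_next = (ds.xy_a[slots + 1] + ds.xy_b[slots + 1]) / 2
    da = np.linalg.norm(ds.xy_a[slots] - c_next, axis=1)
    db = np.linalg.norm(ds.xy_b[slots] - c_next, axis=1)
    scores = db - da
    return scores, float(np.nanmean(scores)) if len(scores) else np.nan
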