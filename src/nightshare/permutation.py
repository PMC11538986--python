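"""Day-shift permutation engine and the three intergroup null models.

The engine destroys the temporal concurrency of a dyad while preserving each
track's marginal space use and within-day structure: one track's whole-day
blocks are circularly rotated by a random number of days.  Blocks are
anchored at local noon (configurable) so that each block contains one intact
night — the wrap seam then falls in the middle of a day instead of splicing
a night from two different evenings.

Three nulls are built on top of it: (1) attraction/avoidance — dyadic
movement metrics vs their day-shifted distribution; (2) sleeping-site choice
— the proportion of co-tracked nights a dyad shares a site, with the shifted
group's nightly site assignments re-derived from its shifted coordinates;
(3) site-specific post-sharing movement — next-day metrics conditioned on
(permuted) sharing of one particular site.

Following the study's convention, "significance" is an empirical value
falling outside the 90% inter-quantile band of the null, and one-sided
permutation p-values are reported in both directions with the add-one
correction (1+k)/(n+1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import AnalysisConfig, in_window
from .io import get_logger
from .preprocess import Trajectory
from .sites import assign_to_sites

__all__ = ["NullDistribution", "day_shift", "build_null", "sharing_null",
           "post_sharing_null", "make_metric", "METRIC_NAMES",
           "aligned_day_blocks", "random_offsets"]

log = get_logger()


@dataclass
class NullDistribution:
    """A permutation null with its empirical value and p-values."""

    metric: str
    empirical: float
    values: np.ndarray            # one metric value per permutation
    p_low: float                  # add-one proportion(null <= empirical)
    p_high: float                 # add-one proportion(null >= empirical)
    band: tuple[float, float]     # null inter-quantile band (default 5th-95th)
    significant: bool             # empirical strictly outside the band
    abstained: bool = False
    n_instances: int | None = None

    @classmethod
    def from_values(cls, metric: str, empirical: float, values,
                    band_q=(0.05, 0.95), **kw) -> "NullDistribution":
        values = np.asarray([v for v in values if np.isfinite(v)], float)
        n = len(values)
        if n == 0 or not np.isfinite(empirical):
            return cls(metric, float(empirical), values, np.nan, np.nan,
                       (np.nan, np.nan), False, abstained=True, **kw)
        p_low = (1 + (values <= empirical).sum()) / (n + 1)
        p_high = (1 + (values >= empirical).sum()) / (n + 1)
        lo, hi = np.quantile(values, band_q)
        sig = bool(empirical < lo or empirical > hi)
        return cls(metric, float(empirical), values, float(p_low),
                   float(p_high), (float(lo), float(hi)), sig, **kw)

    @classmethod
    def abstention(cls, metric: str, n_instances: int = 0) -> "NullDistribution":
        """Explicit refusal to produce a p-value (too few instances)."""
        return cls(metric, np.nan, np.array([]), np.nan, np.nan,
                   (np.nan, np.nan), False, abstained=True,
                   n_instances=n_instances)


# ---------------------------------------------------------------------------
# day blocks

def _block_start(traj: Trajectory, day_start_hour: int) -> int:
    times = traj.times
    m = times.hour * 60 + times.minute
    hit = np.flatnonzero(m == day_start_hour * 60)
    if len(hit) == 0:
        raise ValueError("trajectory never touches the block boundary time")
    return int(hit[0])

def _blocks_per_day(traj: Trajectory) -> int:
    return int(pd.Timedelta(days=1) / traj.interval)


def day_shift(traj: Trajectory, offset_days: int,
              day_start_hour: int = 12) -> Trajectory:
    """Circularly rotate whole-day blocks of a trajectory.

    ``offset_days`` must satisfy 1 <= offset < number of complete blocks (a
    full rotation is the identity and is disallowed).  The returned
    trajectory is trimmed to complete blocks; within-day structure is
    untouched and the multiset of (time-of-day, x, y) is preserved.
    """
    spd = _blocks_per_day(traj)
    i0 = _block_start(traj, day_start_hour)
    nb = (len(traj) - i0) // spd
    if nb < 2:
        raise ValueError("need at least 2 complete day blocks")
    if not 1 <= offset_days < nb:
        raise ValueError(f"offset_days must be in [1, {nb - 1}], got {offset_days}")
    sl = slice(i0, i0 + nb * spd)
    xy = np.roll(traj.xy[sl].reshape(nb, spd, 2), offset_days, axis=0).reshape(-1, 2)
    flag = np.roll(traj.flag[sl].reshape(nb, spd), offset_days, axis=0).ravel()
    return replace(traj, start=traj.times[i0], xy=xy, flag=flag)


def aligned_day_blocks(track_a: Trajectory, track_b: Trajectory,
                       day_start_hour: int = 12):
    """Trim two tracks to their common complete-day-block span.

    Returns ``(A, B, times)`` with A, B of shape (n_blocks, slots_per_day, 2)
    on an identical grid.
    """
    if track_a.interval != track_b.interval:
        raise ValueError("tracks must share a sampling interval")
    spd = _blocks_per_day(track_a)
    start = max(track_a.start, track_b.start)
    end = min(track_a.times[-1], track_b.times[-1])
    if start >= end:
        log.warning("aligned_day_blocks: disjoint time coverage")
        return None
    def cut(t: Trajectory):
        j0 = int((start - t.start) / t.interval)
        j1 = int((end - t.start) / t.interval) + 1
        return t.xy[j0:j1], t.times[j0:j1]
    xa, times = cut(track_a)
    xb, _ = cut(track_b)
    m = times.hour * 60 + times.minute
    hit = np.flatnonzero(m == day_start_hour * 60)
    if len(hit) == 0:
        return None
    i0 = int(hit[0])
    nb = (len(times) - i0) // spd
    if nb < 2:
        return None
    sl = slice(i0, i0 + nb * spd)
    return (xa[sl].reshape(nb, spd, 2), xb[sl].reshape(nb, spd, 2), times[sl])


def random_offsets(n_blocks: int, n_perm: int, rng) -> np.ndarray:
    """Day offsets in [1, n_blocks-1], without replacement when possible."""
    avail = n_blocks - 1
    if avail >= n_perm:
        return rng.choice(np.arange(1, n_blocks), size=n_perm, replace=False)
    log.warning("random_offsets: only %d distinct offsets for %d permutations; "
                "sampling with replacement", avail, n_perm)
    return rng.integers(1, n_blocks, size=n_perm)


# ---------------------------------------------------------------------------
# dyadic metrics

METRIC_NAMES = ("mean_distance", "assoc_time", "within_distance",
                "heading_diff", "step_diff")


def _headings_steps(xy: np.ndarray, min_step_m: float):
    """Heading (deg, atan2 convention: 0=east, CCW) and step length at each
    point, from the displacement arriving there; NaN below ``min_step_m``."""
    d = np.diff(xy, axis=0)
    step = np.hypot(d[:, 0], d[:, 1])
    head = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    head[step < min_step_m] = np.nan
    return (np.r_[np.nan, head], np.r_[np.nan, step])


def circular_diff_deg(a, b) -> np.ndarray:
    """Absolute circular difference of two heading arrays, folded to [0, 180]."""
    d = np.abs(a - b) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


def make_metric(name: str, config: AnalysisConfig | None = None,
                radius_m: float = 600.0):
    """Build a metric function ``f(xy_a, xy_b, times) -> float``.

    The five dyadic metrics of the attraction/avoidance null: overall mean
    distance, proportion of time in association (within the response
    radius), and — restricted to within-radius timestamps — mean distance,
    mean heading difference and mean absolute step-length difference.
    """
    config = config or AnalysisConfig()
    ms = config.min_step_m

    def dist(xa, xb):
        return np.hypot(xa[:, 0] - xb[:, 0], xa[:, 1] - xb[:, 1])

    if name == "mean_distance":
        def f(xa, xb, times=None):
            return float(np.nanmean(dist(xa, xb)))
    elif name == "assoc_time":
        def f(xa, xb, times=None):
            d = dist(xa, xb)
            ok = np.isfinite(d)
            return float((d[ok] <= radius_m).mean()) if ok.any() else np.nan
    elif name == "within_distance":
        def f(xa, xb, times=None):
            d = dist(xa, xb)
            w = d[np.isfinite(d) & (d <= radius_m)]
            return float(w.mean()) if len(w) else np.nan
    elif name == "heading_diff":
        def f(xa, xb, times=None):
            d = dist(xa, xb)
            ha, _ = _headings_steps(xa, ms)
            hb, _ = _headings_steps(xb, ms)
            hd = circular_diff_deg(ha, hb)
            w = hd[np.isfinite(hd) & np.isfinite(d) & (d <= radius_m)]
            return float(w.mean()) if len(w) else np.nan
    elif name == "step_diff":
        def f(xa, xb, times=None):
            d = dist(xa, xb)
            _, sa = _headings_steps(xa, ms)
            _, sb = _headings_steps(xb, ms)
            sd = np.abs(sa - sb)
            w = sd[np.isfinite(sd) & np.isfinite(d) & (d <= radius_m)]
            return float(w.mean()) if len(w) else np.nan
    else:
        raise KeyError(f"unknown metric {name!r}; have {METRIC_NAMES}")
    f.__name__ = name
    return f


def build_null(track_a: Trajectory, track_b: Trajectory, metric_fn,
               n_perm: int = 1000, seed: int = 0,
               config: AnalysisConfig | None = None) -> NullDistribution:
    """Attraction/avoidance null: the metric under day-shifts of one track.

    The track with fewer tracking days (non-missing points; ties -> second
    track) is the one shifted.  Offsets are drawn without replacement when
    enough distinct day offsets exist.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    ab = aligned_day_blocks(track_a, track_b, config.day_start_hour)
    if ab is None:
        return NullDistribution.abstention(getattr(metric_fn, "__name__", "metric"))
    A, B, times = ab
    na = (~np.isnan(A[..., 0])).sum()
    nb_pts = (~np.isnan(B[..., 0])).sum()
    shift_b = nb_pts <= na
    nb = A.shape[0]
    emp = metric_fn(A.reshape(-1, 2), B.reshape(-1, 2), times)
    vals = np.empty(n_perm)
    offs = random_offsets(nb, n_perm, rng)
    for i, k in enumerate(offs):
        if shift_b:
            vals[i] = metric_fn(A.reshape(-1, 2),
                                np.roll(B, k, axis=0).reshape(-1, 2), times)
        else:
            vals[i] = metric_fn(np.roll(A, k, axis=0).reshape(-1, 2),
                                B.reshape(-1, 2), times)
    return NullDistribution.from_values(getattr(metric_fn, "__name__", "metric"),
                                        emp, vals, config.null_band)


# ---------------------------------------------------------------------------
# sleeping-site choice null

def sharing_null(night_records_a: pd.DataFrame, night_records_b: pd.DataFrame,
                 site_assigner, n_perm: int = 1000, seed: int = 0,
                 config: AnalysisConfig | None = None) -> NullDistribution:
    """Null for sleeping-site choice: proportion of co-tracked nights shared.

    For each day-shift replicate the shifted group's nightly assignments are
    re-derived and the dyad's proportion of shared nights recomputed.  With
    noon-anchored blocks a day shift maps every intact night onto a new
    date, so the replicate assignment sequence is the empirical one rotated.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    dates_all = pd.to_datetime(
        list(night_records_a["night_date"]) + list(night_records_b["night_date"]))
    if len(dates_all) == 0:
        return NullDistribution.abstention("sharing")
    dates = pd.date_range(dates_all.min(), dates_all.max(), freq="1D")
    codes: dict = {}   # one shared site coding for both groups
    def seq(records):
        assigned = site_assigner(records)
        lut = {}
        for d, s in zip(pd.to_datetime(records["night_date"]).dt.date, assigned):
            if s is not None and not (isinstance(s, float) and np.isnan(s)):
                lut[d] = codes.setdefault(s, len(codes))
        return np.array([lut.get(d.date(), -1) for d in dates])
    sa, sb = seq(night_records_a), seq(night_records_b)

    def proportion(x, y):
        ok = (x >= 0) & (y >= 0)
        return float((x[ok] == y[ok]).mean()) if ok.any() else np.nan

    emp = proportion(sa, sb)
    n = len(dates)
    offs = random_offsets(n, n_perm, rng)
    vals = np.array([proportion(sa, np.roll(sb, k)) for k in offs])
    return NullDistribution.from_values("sharing", emp, vals, config.null_band)


# ---------------------------------------------------------------------------
# site-specific post-sharing null

def post_sharing_null(track_a: Trajectory, track_b: Trajectory,
                      night_sites_a: pd.Series, night_sites_b: pd.Series,
                      site_id, metric_fn, n_perm: int = 1000, seed: int = 0,
                      min_instances: int = 20,
                      config: AnalysisConfig | None = None) -> NullDistribution:
    """Next-day movement null conditional on (permuted) sharing of one site.

    ``night_sites_*`` map night dates to site ids.  For every permutation the
    day-shifted pairing is scanned for nights on which both groups are
    assigned to ``site_id``; the metric is evaluated on the pooled day-window
    points of the following days.  If fewer than ``min_instances`` permuted
    sharing instances exist in total, the test abstains rather than return
    an unreliable p-value.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    ab = aligned_day_blocks(track_a, track_b, config.day_start_hour)
    if ab is None:
        return NullDistribution.abstention("post_sharing")
    A, B, times = ab
    nb, spd, _ = A.shape
    block_times = times[:spd]
    # block j runs noon(day j) -> noon(day j+1) and holds the intact night of
    # day j; the *following* day's free-travel window is therefore the tail of
    # block j (its morning half) plus the head of block j+1 (its afternoon).
    mask_am = in_window(block_times, (config.foraging_window[0], "12:00"))
    mask_pm = in_window(block_times, ("12:00", config.foraging_window[1]), closed="both")
    block_dates = times[::spd].normalize()

    def site_seq(mapping: pd.Series):
        m = {pd.Timestamp(k).date(): v for k, v in mapping.items()}
        return np.array([1 if m.get(d.date()) == site_id else 0 for d in block_dates])

    qa, qb = site_seq(night_sites_a), site_seq(night_sites_b)
    sep = np.full((1, 2), np.nan)   # breaks displacement steps between days

    def metric_after(shared_blocks: np.ndarray, Bv: np.ndarray):
        js = shared_blocks[shared_blocks + 1 < nb]
        if len(js) == 0:
            return np.nan, 0
        xa = np.concatenate(sum(([A[j][mask_am], A[j + 1][mask_pm], sep]
                                 for j in js), []))
        xb = np.concatenate(sum(([Bv[j][mask_am], Bv[j + 1][mask_pm], sep]
                                 for j in js), []))
        return metric_fn(xa, xb, None), len(js)

    emp, emp_n = metric_after(np.flatnonzero((qa == 1) & (qb == 1)), B)
    offs = random_offsets(nb, n_perm, rng)
    vals = np.full(n_perm, np.nan)
    total = 0
    for i, k in enumerate(offs):
        qbk = np.roll(qb, k)
        shared = np.flatnonzero((qa == 1) & (qbk == 1))
        vals[i], n_inst = metric_after(shared, np.roll(B, k, axis=0))
        total += n_inst
    if total < min_instances:
        log.info("post_sharing_null(%s): %d permuted instances < %d — abstaining",
                 site_id, total, min_instances)
        return NullDistribution.abstention(
            getattr(metric_fn, "__name__", "post_sharing"), total)
    nd = NullDistribution.from_values(getattr(metric_fn, "__name__", "metric"),
                                      emp, vals, config.null_band,
                                      n_instances=total)
    return nd
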