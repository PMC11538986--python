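"""Regularization and cleaning of raw GPS fixes into gridded trajectories.

A :class:`Trajectory` lives on a strictly regular local-time grid (15 min by
default) anchored at local midnight, with per-point provenance flags.  The
cleaning chain is ``regularize -> correct_anomalies -> remove_jitter``;
group-level tracks are then built from the member trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import AnalysisConfig, in_window
from .io import GpsFix, fixes_to_frame, get_logger

__all__ = [
    "Trajectory", "OBSERVED", "INTERPOLATED", "CORRECTED", "MISSING",
    "regularize", "correct_anomalies", "remove_jitter", "build_group_track",
    "clean_individual",
]

log = get_logger()

MISSING, OBSERVED, INTERPOLATED, CORRECTED = -1, 0, 1, 2
FLAG_NAMES = {MISSING: "missing", OBSERVED: "observed",
              INTERPOLATED: "interpolated", CORRECTED: "corrected"}


@dataclass
class Trajectory:
    """A regular 15-min location series for one individual (or group)."""

    individual_id: str
    group_id: str
    start: pd.Timestamp          # first grid timestamp, tz-aware
    interval: pd.Timedelta
    xy: np.ndarray               # (n, 2) float, NaN where missing
    flag: np.ndarray             # (n,) int8 provenance codes

    def __post_init__(self):
        self.xy = np.asarray(self.xy, float)
        self.flag = np.asarray(self.flag, np.int8)
        if self.xy.shape != (len(self.flag), 2):
            raise ValueError("xy and flag shapes disagree")

    def __len__(self) -> int:
        return len(self.flag)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self), freq=self.interval)

    def copy(self) -> "Trajectory":
        return replace(self, xy=self.xy.copy(), flag=self.flag.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "individual_id": self.individual_id, "group_id": self.group_id,
            "timestamp": self.times, "x": self.xy[:, 0], "y": self.xy[:, 1],
            "flag": [FLAG_NAMES[f] for f in self.flag],
        })


def _as_frame(fixes) -> pd.DataFrame:
    if isinstance(fixes, pd.DataFrame):
        return fixes
    if fixes and isinstance(fixes[0], GpsFix):
        return fixes_to_frame(list(fixes))
    raise ValueError("expected a DataFrame or a list of GpsFix")


def regularize(fixes, interval=None, max_gap: int = 4,
               config: AnalysisConfig | None = None) -> list[Trajectory]:
    """Snap fixes of each individual to a common global grid and fill gaps.

    The grid is anchored at local midnight of the earliest fix across all
    individuals (so trajectories are mutually synchronized).  Each fix is
    assigned to the nearest grid slot within interval/2; ties and duplicate
    slots keep the first fix.  Interior gaps of at most ``max_gap`` intervals
    are linearly interpolated and flagged; longer gaps stay missing.
    """
    config = config or AnalysisConfig()
    interval = pd.Timedelta(interval) if interval is not None else config.interval
    df = _as_frame(fixes)
    if df.empty or len(df) < 2:
        raise ValueError("regularize needs at least 2 fixes")
    df = df[df["valid"].astype(bool)]
    t0 = df["timestamp"].min().tz_convert(config.tzinfo).normalize()
    t1 = df["timestamp"].max()
    out = []
    for (ind, grp), g in df.groupby(["individual_id", "group_id"], sort=True):
        ts = pd.DatetimeIndex(g["timestamp"]).tz_convert(config.tzinfo)
        slot = np.round((ts - t0) / interval).astype(int)
        offset = np.abs(ts - (t0 + slot * interval))
        ok = offset <= interval / 2
        slot, xs, ys = slot[ok], g["x"].to_numpy(float)[ok], g["y"].to_numpy(float)[ok]
        first = np.unique(slot, return_index=True)[1]
        slot, xs, ys = slot[first], xs[first], ys[first]
        if len(slot) < 2:
            log.warning("regularize: %s has <2 usable fixes, skipped", ind)
            continue
        n = slot.max() - slot.min() + 1
        base = slot.min()
        xy = np.full((n, 2), np.nan)
        flag = np.full(n, MISSING, np.int8)
        xy[slot - base, 0], xy[slot - base, 1] = xs, ys
        flag[slot - base] = OBSERVED
        _interpolate_gaps(xy, flag, max_gap)
        out.append(Trajectory(str(ind), str(grp), t0 + base * interval, interval, xy, flag))
    return out


def _interpolate_gaps(xy: np.ndarray, flag: np.ndarray, max_gap: int) -> None:
    """Linear interpolation of interior missing runs of length <= max_gap."""
    miss = flag == MISSING
    if not miss.any():
        return
    idx = np.flatnonzero(miss)
    # split into consecutive runs
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        i0, i1 = run[0] - 1, run[-1] + 1
        if i0 < 0 or i1 >= len(flag) or len(run) > max_gap:
            continue
        w = (run - i0) / (i1 - i0)
        xy[run] = xy[i0] + w[:, None] * (xy[i1] - xy[i0])
        flag[run] = INTERPOLATED


def correct_anomalies(traj: Trajectory, max_speed_mps: float = 3.0) -> Trajectory:
    """Replace out-and-back GPS spikes by their neighbours' midpoint.

    A point is a spike when the displacement to it and back both imply speeds
    above ``max_speed_mps`` while its neighbours are mutually reachable below
    that speed — i.e. the track jumps out and returns.  A pure speed filter
    would also delete genuine flight responses; the spike pattern does not.
    """
    traj = traj.copy()
    dt = traj.interval.total_seconds()
    lim = max_speed_mps * dt
    xy = traj.xy
    d_in = np.linalg.norm(xy[1:-1] - xy[:-2], axis=1)
    d_out = np.linalg.norm(xy[2:] - xy[1:-1], axis=1)
    d_skip = np.linalg.norm(xy[2:] - xy[:-2], axis=1)
    spike = (d_in > lim) & (d_out > lim) & (d_skip <= 2 * lim)
    spike &= ~np.isnan(d_in) & ~np.isnan(d_out)
    i = np.flatnonzero(spike) + 1
    if len(i):
        xy[i] = (xy[i - 1] + xy[i + 1]) / 2
        traj.flag[i] = CORRECTED
        log.info("correct_anomalies: %s: %d spike(s) replaced", traj.individual_id, len(i))
    return traj


def remove_jitter(traj: Trajectory, night_window=("20:00", "04:00"),
                  jitter_radius_m: float = 20.0) -> Trajectory:
    """Snap night-time points within ``jitter_radius_m`` of the night median
    to that median.  Daytime points are never altered."""
    traj = traj.copy()
    times = traj.times
    night = in_window(times, night_window)
    # a night = the window starting on one evening; label points by that date
    m = times.hour * 60 + times.minute
    evening = times.normalize().where(m >= 12 * 60, times.normalize() - pd.Timedelta(days=1))
    lab = np.where(night, evening.astype("int64"), -1)
    for key in np.unique(lab):
        if key < 0:
            continue
        sel = np.flatnonzero(lab == key)
        pts = traj.xy[sel]
        good = ~np.isnan(pts[:, 0])
        if good.sum() < 2:
            continue
        med = np.nanmedian(pts, axis=0)
        close = good & (np.linalg.norm(pts - med, axis=1) <= jitter_radius_m)
        moved = close & (np.linalg.norm(pts - med, axis=1) > 0)
        traj.xy[sel[close]] = med
        traj.flag[sel[moved & (traj.flag[sel] == OBSERVED)]] = CORRECTED
    return traj


def clean_individual(fix_frame, config: AnalysisConfig | None = None) -> list[Trajectory]:
    """Full per-individual cleaning chain with the configured defaults."""
    config = config or AnalysisConfig()
    trajs = regularize(fix_frame, config.interval, config.max_gap_intervals, config)
    return [
        remove_jitter(correct_anomalies(t, config.max_speed_mps),
                      config.night_window, config.jitter_radius_m)
        for t in trajs
    ]


def build_group_track(members: list[Trajectory]) -> Trajectory:
    """One representative location per timestamp for a group.

    Wherever several collared members have simultaneous data, the member with
    the longest total data duration represents the group (group-level
    duplicates are removed in favour of the longer record).
    """
    if not members:
        raise ValueError("build_group_track needs at least one member")
    if len(members) == 1:
        m = members[0]
        return replace(m.copy(), individual_id=f"group:{m.group_id}")
    interval = members[0].interval
    order = sorted(members, key=lambda t: (~np.isnan(t.xy[:, 0])).sum(), reverse=True)
    start = min(t.start for t in members)
    end = max(t.times[-1] for t in members)
    n = int((end - start) / interval) + 1
    xy = np.full((n, 2), np.nan)
    flag = np.full(n, MISSING, np.int8)
    for m in reversed(order):  # lowest priority first, best member overwrites
        i0 = int((m.start - start) / interval)
        have = ~np.isnan(m.xy[:, 0])
        sl = np.arange(i0, i0 + len(m))[have]
        xy[sl] = m.xy[have]
        flag[sl] = m.flag[have]
    return Trajectory(f"group:{members[0].group_id}", members[0].group_id,
                      start, interval, xy, flag)
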