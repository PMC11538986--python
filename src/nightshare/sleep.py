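"""Posture-angle sleep classification and nightly sleep metrics.

Each one-minute accelerometer burst is reduced to its mean gravity vector;
the posture angle is the elevation of that vector,
``arctan(mean_az / sqrt(mean_ax^2 + mean_ay^2))``.  A minute is classified
as sleep when it lies inside a run of at least ``window_min`` consecutive
minutes whose successive absolute angle changes all stay below
``angle_threshold_deg`` — sustained postural stability — and as wake
otherwise; minutes without a burst are missing.

Nightly metrics over the fixed sleep period (21:00-05:00 by default):
total sleep time (sleep minutes), sleep efficiency (sleep fraction of the
classified minutes), fragmentation (wake bouts of >= 2 min per hour of
sleep) and sleep onset/offset (bounds of the first/last sustained sleep run
inside a wider search window).  Dyadic synchronization is the fraction of
jointly classified minutes in the same state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig, in_window, parse_hhmm
from .io import get_logger

__all__ = ["posture_angles", "classify_minutes", "sleep_metrics",
           "nightly_sleep_table", "synchronization", "build_effect_table",
           "summarize_sharing_effects"]

log = get_logger()


def posture_angles(bursts) -> pd.DataFrame:
    """Per-minute posture angle (degrees) from bursts or a burst-mean frame.

    Accepts a list of :class:`AccelBurst` or a DataFrame with columns
    individual_id, timestamp, mean_ax, mean_ay, mean_az.  All-zero bursts
    (dead sensor) yield a missing angle.
    """
    if isinstance(bursts, pd.DataFrame):
        df = bursts.copy()
    else:
        df = pd.DataFrame({
            "individual_id": [b.individual_id for b in bursts],
            "timestamp": [b.timestamp for b in bursts],
            "mean_ax": [np.mean(b.ax) for b in bursts],
            "mean_ay": [np.mean(b.ay) for b in bursts],
            "mean_az": [np.mean(b.az) for b in bursts],
        })
    horiz = np.hypot(df["mean_ax"], df["mean_ay"])
    norm = np.hypot(horiz, df["mean_az"])
    angle = np.degrees(np.arctan2(df["mean_az"], horiz))
    dead = norm < 1e-3
    if dead.any():
        log.warning("posture_angles: %d all-zero burst(s) -> missing", int(dead.sum()))
        angle[dead] = np.nan
    return pd.DataFrame({"individual_id": df["individual_id"],
                         "timestamp": df["timestamp"], "angle_deg": angle})


def classify_minutes(bursts, angle_threshold_deg: float = 5.0,
                     window_min: int = 5) -> pd.DataFrame:
    """Minute-state series per individual: sleep / wake / missing.

    Returns a frame with individual_id, timestamp (continuous 1-min grid
    spanning each individual's data), state and angle_deg.
    """
    ang = posture_angles(bursts) if not (
        isinstance(bursts, pd.DataFrame) and "angle_deg" in getattr(bursts, "columns", ())
    ) else bursts
    out = []
    for ind, g in ang.groupby("individual_id", sort=True):
        g = g.sort_values("timestamp")
        ts = pd.DatetimeIndex(g["timestamp"]).floor("1min")
        grid = pd.date_range(ts.min(), ts.max(), freq="1min")
        a = pd.Series(g["angle_deg"].to_numpy(), index=ts).reindex(grid).to_numpy()
        state = np.where(np.isnan(a), "missing", "wake").astype(object)
        have = ~np.isnan(a)
        # successive diffs valid only between adjacent non-missing minutes
        small = np.zeros(len(a), bool)          # small[i]: diff (i-1, i) is stable
        small[1:] = (np.abs(np.diff(a)) < angle_threshold_deg) & have[1:] & have[:-1]
        # runs of consecutive small diffs; a run of m diffs spans m+1 minutes
        i = 1
        n = len(a)
        while i < n:
            if not small[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and small[j + 1]:
                j += 1
            if (j - i + 1) + 1 >= window_min:
                state[i - 1: j + 1] = "sleep"
            i = j + 1
        out.append(pd.DataFrame({"individual_id": ind, "timestamp": grid,
                                 "state": state, "angle_deg": a}))
    return pd.concat(out, ignore_index=True)


def _night_key(ts: pd.DatetimeIndex) -> pd.DatetimeIndex:
    """Night (evening) date: minutes before noon belong to the previous day."""
    m = ts.hour * 60 + ts.minute
    return ts.normalize().where(m >= 12 * 60, ts.normalize() - pd.Timedelta(days=1))


def sleep_metrics(states: pd.DataFrame, config: AnalysisConfig | None = None) -> dict | None:
    """Metrics for a single individual-night of minute states.

    Returns None (unusable night) when less than half of the sleep period is
    classified.  Fragmentation is missing (NaN) when no sleep occurred.
    """
    config = config or AnalysisConfig()
    ts = pd.DatetimeIndex(states["timestamp"])
    st = states["state"].to_numpy()
    period = in_window(ts, config.sleep_period)
    period_len = ((parse_hhmm(config.sleep_period[1]) - parse_hhmm(config.sleep_period[0])) % 1440)
    ps = st[period]
    classified = int((ps != "missing").sum())
    if classified < 0.5 * period_len:
        return None
    tst = int((ps == "sleep").sum())
    efficiency = tst / classified
    # wake bouts >= wake_bout_min within the sleep period
    wake = (ps == "wake").astype(int)
    nb = 0
    run = 0
    for v in np.r_[wake, 0]:
        if v:
            run += 1
        else:
            if run >= config.wake_bout_min:
                nb += 1
            run = 0
    frag = nb / (tst / 60) if tst > 0 else np.nan

    search = in_window(ts, config.onset_search)
    onset = offset = None
    sl = (st == "sleep") & search
    idx = np.flatnonzero(sl)
    if len(idx):
        breaks = np.flatnonzero(np.diff(idx) > 1) + 1
        runs = [r for r in np.split(idx, breaks) if len(r) >= config.sleep_window_min]
        if runs:
            onset, offset = ts[runs[0][0]], ts[runs[-1][-1]]
    return {"total_sleep_time_min": tst, "sleep_efficiency": float(efficiency),
            "fragmentation": float(frag), "n_classified": classified,
            "onset": onset, "offset": offset}


def nightly_sleep_table(states: pd.DataFrame,
                        config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-individual-night sleep metrics; unusable nights are dropped."""
    config = config or AnalysisConfig()
    rows = []
    key = _night_key(pd.DatetimeIndex(states["timestamp"]))
    for (ind, night), g in states.groupby([states["individual_id"], key]):
        m = sleep_metrics(g, config)
        if m is None:
            continue
        rows.append({"individual_id": ind, "night_date": night.date(), **m})
    return pd.DataFrame(rows)


def synchronization(states_a: pd.DataFrame, states_b: pd.DataFrame,
                    sleep_period=("21:00", "05:00")) -> float:
    """Fraction of jointly classified sleep-period minutes in the same state."""
    a = states_a.set_index("timestamp")["state"]
    b = states_b.set_index("timestamp")["state"]
    j = pd.concat([a, b], axis=1, keys=["a", "b"], join="inner")
    j = j[in_window(pd.DatetimeIndex(j.index), sleep_period)]
    j = j[(j["a"] != "missing") & (j["b"] != "missing")]
    if len(j) == 0:
        return np.nan
    return float((j["a"] == j["b"]).mean())


def build_effect_table(sleep_nights: pd.DataFrame, night_records: pd.DataFrame,
                       states: pd.DataFrame | None = None,
                       config: AnalysisConfig | None = None):
    """Model-ready tables for the sharing -> sleep-quality analysis.

    ``night_records`` carries per individual-night group_id, site_id and
    shared flags (from the sites module or the simulator truth).  Returns
    (individual_table, dyad_table); the dyad table (cross-group pairs with a
    per-night synchronization score) is empty when ``states`` is omitted.
    """
    config = config or AnalysisConfig()
    rec = night_records.copy()
    rec["night_date"] = pd.to_datetime(rec["night_date"]).dt.date
    sn = sleep_nights.copy()
    sn["night_date"] = pd.to_datetime(sn["night_date"]).dt.date
    ind = sn.merge(rec[["individual_id", "night_date", "group_id", "site_id", "shared"]],
                   on=["individual_id", "night_date"], how="inner")

    dyads = []
    if states is not None and len(ind):
        key = _night_key(pd.DatetimeIndex(states["timestamp"]))
        states = states.assign(_night=key)
        grp = {i: g for i, g in ind.groupby("individual_id")["group_id"].first().items()}
        site = ind.set_index(["individual_id", "night_date"])["site_id"]
        by = {(i, n.date()): g for (i, n), g in states.groupby(["individual_id", "_night"])}
        nights = sorted({n for (_, n) in by})
        inds = sorted(grp)
        for night in nights:
            for a, b in itertools.combinations(inds, 2):
                if grp[a] == grp[b]:
                    continue
                ga, gb = by.get((a, night)), by.get((b, night))
                if ga is None or gb is None:
                    continue
                score = synchronization(ga, gb, config.sleep_period)
                if np.isnan(score):
                    continue
                sa = site.get((a, night), None)
                sb = site.get((b, night), None)
                dyads.append({"individual_a": a, "individual_b": b,
                              "night_date": night, "synchronization": score,
                              "same_site": sa is not None and sa == sb})
    dyad_table = pd.DataFrame(dyads, columns=["individual_a", "individual_b",
                                              "night_date", "synchronization",
                                              "same_site"])
    return ind, dyad_table


def summarize_sharing_effects(effect_table: pd.DataFrame, n_boot: int = 1000,
                              seed: int = 0,
                              metrics=("total_sleep_time_min", "sleep_efficiency",
                                       "fragmentation")) -> pd.DataFrame:
    """Shared-minus-unshared mean contrasts with individual-block bootstrap CIs.

    A descriptive summary of the sharing effect: nights are grouped by
    individual and whole individuals resampled with replacement, which
    respects the repeated-measures structure.  95% percentile intervals.
    """
    rng = np.random.default_rng(seed)
    df = effect_table.copy()
    df["shared"] = df["shared"].astype(bool)
    inds = df["individual_id"].unique()
    groups = {i: g for i, g in df.groupby("individual_id")}
    rows = []
    for metric in metrics:
        sub = df[np.isfinite(df[metric])]
        diff = (sub.loc[sub["shared"], metric].mean()
                - sub.loc[~sub["shared"], metric].mean())
        boots = []
        for _ in range(n_boot):
            pick = rng.choice(inds, size=len(inds), replace=True)
            r = pd.concat([groups[i] for i in pick], ignore_index=True)
            r = r[np.isfinite(r[metric])]
            s, u = r.loc[r["shared"], metric], r.loc[~r["shared"], metric]
            if len(s) and len(u):
                boots.append(s.mean() - u.mean())
        boots = np.asarray(boots)
        lo, hi = (np.quantile(boots, [0.025, 0.975]) if len(boots)
                  else (np.nan, np.nan))
        rows.append({"metric": metric, "difference": float(diff),
                     "ci_lo": float(lo), "ci_hi": float(hi),
                     "n_shared": int(df["shared"].sum()),
                     "n_unshared": int((~df["shared"]).sum()),
                     "n_boot_used": len(boots)})
    return pd.DataFrame(rows)
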