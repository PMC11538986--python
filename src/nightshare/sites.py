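"""Sleeping-site identification from nightly GPS centroids.

Each individual-night gets a centroid (mean of fixes in the 20:00-04:00
window); centroids are clustered with hierarchical agglomerative clustering
(complete linkage by default, tree cut at a fixed height in metres) and each
cluster becomes a sleeping site.  A night is "shared" when at least two
distinct groups are assigned to the same site on the same night.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .config import in_window
from .preprocess import Trajectory
from .io import get_logger

__all__ = ["nightly_centroids", "cluster_sites", "flag_shared_nights",
           "assign_to_sites"]

log = get_logger()


def nightly_centroids(traj: Trajectory, night_window=("20:00", "04:00"),
                      min_fixes: int = 8) -> pd.DataFrame:
    """One centroid per night with at least ``min_fixes`` usable fixes.

    The night date is the date at the start of the window (the evening);
    fixes after midnight count toward the previous evening's night.
    """
    times = traj.times
    mask = in_window(times, night_window) & ~np.isnan(traj.xy[:, 0])
    m = times.hour * 60 + times.minute
    evening = times.normalize().where(m >= 12 * 60, times.normalize() - pd.Timedelta(days=1))
    rows = []
    df = pd.DataFrame({"evening": evening[mask], "x": traj.xy[mask, 0],
                       "y": traj.xy[mask, 1]})
    for ev, g in df.groupby("evening", sort=True):
        if len(g) < min_fixes:
            log.info("nightly_centroids: %s night %s has %d fixes (<%d), skipped",
                     traj.individual_id, ev.date(), len(g), min_fixes)
            continue
        rows.append({"individual_id": traj.individual_id, "group_id": traj.group_id,
                     "night_date": ev.date(), "x": g["x"].mean(), "y": g["y"].mean(),
                     "n_fixes": len(g)})
    return pd.DataFrame(rows, columns=["individual_id", "group_id", "night_date",
                                       "x", "y", "n_fixes"])


def cluster_sites(night_records: pd.DataFrame, cut_m: float = 500.0,
                  method: str = "complete") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster night centroids into sleeping sites.

    Returns ``(sites, nights)``: a site table (site_id, centroid, usage
    counts) and the input records with a ``site_id`` column.  Complete
    linkage bounds the within-site diameter by the cut height.
    """
    if cut_m <= 0:
        raise ValueError("cut_m must be positive")
    rec = night_records.reset_index(drop=True).copy()
    if len(rec) < 2:
        raise ValueError("cluster_sites needs at least 2 night records")
    xy = rec[["x", "y"]].to_numpy(float)
    lab = fcluster(linkage(xy, method=method), t=cut_m, criterion="distance")
    # stable ids ordered by first appearance in (x, y)-sorted order
    order = {}
    for l in lab[np.lexsort((xy[:, 1], xy[:, 0]))]:
        order.setdefault(l, len(order))
    rec["site_id"] = [f"C{order[l]:02d}" for l in lab]
    sites = (rec.groupby("site_id")
             .agg(x=("x", "mean"), y=("y", "mean"), n_nights=("x", "size"),
                  n_groups=("group_id", "nunique"))
             .reset_index())
    return sites, rec


def assign_to_sites(centroids: pd.DataFrame, sites: pd.DataFrame,
                    max_dist_m: float = 500.0) -> pd.Series:
    """Nearest-site assignment of centroids; NaN beyond ``max_dist_m``."""
    sxy = sites[["x", "y"]].to_numpy(float)
    cxy = centroids[["x", "y"]].to_numpy(float)
    d = np.linalg.norm(cxy[:, None, :] - sxy[None, :, :], axis=2)
    j = d.argmin(axis=1)
    out = sites["site_id"].to_numpy()[j].astype(object)
    out[d[np.arange(len(cxy)), j] > max_dist_m] = None
    return pd.Series(out, index=centroids.index, name="site_id")


def flag_shared_nights(nights: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mark nights where >=2 distinct groups used the same site.

    Returns the records with a ``shared`` column plus a symmetric per-dyad
    night table (group_a, group_b, night_date, site_id, same_site).
    """
    rec = nights.copy()
    key = rec.groupby(["night_date", "site_id"])["group_id"].transform("nunique")
    rec["shared"] = (key >= 2) & rec["site_id"].notna()

    groups = sorted(rec["group_id"].unique())
    per_night = (rec.dropna(subset=["site_id"])
                 .groupby(["night_date", "group_id"])["site_id"].first().unstack())
    rows = []
    for a, b in itertools.combinations(groups, 2):
        if a not in per_night.columns or b not in per_night.columns:
            continue
        sub = per_night[[a, b]].dropna()
        for night, (sa, sb) in sub.iterrows():
            rows.append({"group_a": a, "group_b": b, "night_date": night,
                         "site_id": sa if sa == sb else None,
                         "same_site": sa == sb})
    dyads = pd.DataFrame(rows, columns=["group_a", "group_b", "night_date",
                                        "site_id", "same_site"])
    return rec, dyads
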