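"""Readers and writers for tracking CSVs and intermediate tables.

GPS input is a Movebank-style CSV with columns ``individual_id, group_id,
timestamp`` and either projected ``x, y`` (metres) or geographic ``lon, lat``
(decimal degrees).  Accelerometry input is a long CSV with one row per burst
sample: ``individual_id, timestamp, sample_idx, ax, ay, az`` (units g).
Unknown columns are ignored everywhere; timestamps are written ISO-8601.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError", "GpsFix", "AccelBurst", "LocalProjection",
    "read_gps", "read_accel", "write_accel", "write_table", "read_table",
    "fixes_to_frame", "get_logger",
]

EARTH_RADIUS_M = 6_371_008.8


class FormatError(ValueError):
    """Malformed input file (missing column, bad timestamp, ...)."""


def get_logger(name: str = "nightshare", logfile: str | Path | None = None):
    log = logging.getLogger(name)
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        log.addHandler(h)
        log.setLevel(logging.INFO)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
    return log


log = get_logger()


@dataclass
class GpsFix:
    individual_id: str
    group_id: str
    timestamp: pd.Timestamp      # tz-aware
    x: float                     # metres, local planar
    y: float
    valid: bool = True


@dataclass
class AccelBurst:
    """One tri-axial burst (nominally 3 s at 10.54 Hz/axis, ~32 samples)."""
    individual_id: str
    timestamp: pd.Timestamp      # burst start, one per minute
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate_hz: float = 10.54

    def __post_init__(self):
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise FormatError("burst axes differ in length")


class LocalProjection:
    """Local tangent-plane projection of lon/lat onto planar metres.

    An equirectangular projection centred on the data; accurate to well under
    a metre over the tens-of-kilometres extent of a tracking study.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0, self.lat0 = float(lon0), float(lat0)

    @classmethod
    def centred_on(cls, lon, lat) -> "LocalProjection":
        return cls(np.median(lon), np.median(lat))

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon) - self.lon0)
        phi = np.radians(np.asarray(lat) - self.lat0)
        x = EARTH_RADIUS_M * np.cos(np.radians(self.lat0)) * lam
        y = EARTH_RADIUS_M * phi
        return x, y

    def inverse(self, x, y):
        lon = self.lon0 + np.degrees(np.asarray(x) / (EARTH_RADIUS_M * np.cos(np.radians(self.lat0))))
        lat = self.lat0 + np.degrees(np.asarray(y) / EARTH_RADIUS_M)
        return lon, lat


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _parse_timestamps(raw: pd.Series, path) -> pd.Series:
    ts = pd.to_datetime(raw, errors="coerce", utc=False, format="ISO8601")
    bad = ts.isna() & raw.notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header = line 1
        raise FormatError(f"{path}: unparseable timestamp {raw[bad].iloc[0]!r} at line {line}")
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize("UTC")
    return ts


def read_gps(path: str | Path, projection: LocalProjection | None = None) -> list[GpsFix]:
    """Read a GPS CSV into a sorted, de-duplicated list of fixes.

    lon/lat inputs are projected to planar metres (a local projection centred
    on the data unless one is supplied).  Duplicate (individual, timestamp)
    rows keep the first occurrence.
    """
    df = pd.read_csv(path)
    _require(df, ["individual_id", "group_id", "timestamp"], path)
    df["timestamp"] = _parse_timestamps(df["timestamp"], path)
    if {"x", "y"}.issubset(df.columns):
        x, y = df["x"].astype(float), df["y"].astype(float)
    elif {"lon", "lat"}.issubset(df.columns):
        if projection is None:
            projection = LocalProjection.centred_on(df["lon"], df["lat"])
        x, y = projection.forward(df["lon"], df["lat"])
        x, y = pd.Series(x, index=df.index), pd.Series(y, index=df.index)
    else:
        raise FormatError(f"{path}: need either x,y or lon,lat columns")
    df = df.assign(x=x, y=y)
    if "valid" not in df.columns:
        df["valid"] = True
    n0 = len(df)
    df = df.sort_values(["individual_id", "timestamp"], kind="stable")
    df = df.drop_duplicates(["individual_id", "timestamp"], keep="first")
    if len(df) < n0:
        log.info("read_gps: dropped %d duplicate fixes", n0 - len(df))
    return [
        GpsFix(str(r.individual_id), str(r.group_id), r.timestamp,
               float(r.x), float(r.y), bool(r.valid))
        for r in df.itertuples(index=False)
    ]


def fixes_to_frame(fixes: list[GpsFix]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [f.individual_id for f in fixes],
            "group_id": [f.group_id for f in fixes],
            "timestamp": [f.timestamp for f in fixes],
            "x": [f.x for f in fixes],
            "y": [f.y for f in fixes],
            "valid": [f.valid for f in fixes],
        }
    )


def read_accel(path: str | Path) -> list[AccelBurst]:
    """Read long-format burst CSV; bursts with mismatched axis lengths are
    rejected (counted and logged), not fatal."""
    df = pd.read_csv(path)
    _require(df, ["individual_id", "timestamp", "sample_idx", "ax", "ay", "az"], path)
    df["timestamp"] = _parse_timestamps(df["timestamp"], path)
    bursts, rejected = [], 0
    for (ind, ts), g in df.groupby(["individual_id", "timestamp"], sort=True):
        g = g.sort_values("sample_idx")
        ax = g["ax"].dropna().to_numpy(float)
        ay = g["ay"].dropna().to_numpy(float)
        az = g["az"].dropna().to_numpy(float)
        if not (len(ax) == len(ay) == len(az)):
            rejected += 1
            continue
        bursts.append(AccelBurst(str(ind), ts, ax, ay, az))
    if rejected:
        log.warning("read_accel: rejected %d burst(s) with axis-length mismatch", rejected)
    return bursts


def write_accel(bursts: list[AccelBurst], path: str | Path) -> None:
    rows = []
    for b in bursts:
        n = len(b.ax)
        rows.append(pd.DataFrame({
            "individual_id": b.individual_id,
            "timestamp": b.timestamp.isoformat(),
            "sample_idx": np.arange(n),
            "ax": b.ax, "ay": b.ay, "az": b.az,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


# --- intermediate tables ---------------------------------------------------
# schema name -> (ordered columns, timestamp-typed columns)
SCHEMAS: dict[str, tuple[list[str], list[str]]] = {
    "gps": (["individual_id", "group_id", "timestamp", "x", "y", "valid"], ["timestamp"]),
    "sites": (["site_id", "x", "y", "n_nights", "n_groups"], []),
    "nights": (["individual_id", "group_id", "night_date", "x", "y", "n_fixes",
                "site_id", "shared"], []),
    "interactions": (["group_a", "group_b", "start", "end", "duration_h",
                      "cohesive", "preceded_by_shared_night", "front_behind_mean"],
                     ["start", "end"]),
    "sleep_nights": (["individual_id", "group_id", "night_date", "total_sleep_time_min",
                      "sleep_efficiency", "fragmentation", "onset", "offset",
                      "shared", "site_id"], []),
    "dyad_nights": (["individual_a", "individual_b", "night_date",
                     "synchronization", "same_site"], []),
}


def write_table(records: pd.DataFrame, path: str | Path, schema_name: str) -> None:
    """Write an intermediate table with a fixed column order and ISO timestamps."""
    cols, ts_cols = SCHEMAS[schema_name]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise FormatError(f"schema {schema_name!r}: records missing column(s) {missing}")
    out = records[cols].copy()
    for c in ts_cols:
        out[c] = pd.to_datetime(out[c]).map(lambda t: t.isoformat())
    out.to_csv(path, index=False)


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    cols, ts_cols = SCHEMAS[schema_name]
    df = pd.read_csv(path)
    _require(df, cols, path)
    for c in ts_cols:
        df[c] = _parse_timestamps(df[c], path)
    return df[cols]
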