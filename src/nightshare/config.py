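"""Global analysis configuration.

All spatial thresholds are in metres and all time-of-day windows are local
clock times ("HH:MM" strings).  Windows may wrap past midnight (e.g. the
night window 20:00-04:00); membership tests handle the wrap.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["AnalysisConfig", "parse_hhmm", "minute_of_day", "in_window"]


def parse_hhmm(s: str) -> int:
    """'HH:MM' -> minutes since local midnight."""
    h, m = s.split(":")
    v = int(h) * 60 + int(m)
    if not 0 <= v < 1440:
        raise ValueError(f"time of day out of range: {s!r}")
    return v


def minute_of_day(times) -> np.ndarray:
    """Minutes since local midnight for a tz-aware DatetimeIndex."""
    return np.asarray(times.hour) * 60 + np.asarray(times.minute)


def in_window(times, window: tuple[str, str], closed: str = "left") -> np.ndarray:
    """Boolean mask of timestamps falling in a (possibly wrapping) window.

    ``closed='left'`` means [start, end); ``'both'`` means [start, end].
    """
    lo, hi = parse_hhmm(window[0]), parse_hhmm(window[1])
    m = minute_of_day(times)
    upper = (m <= hi) if closed == "both" else (m < hi)
    if lo <= hi:
        return (m >= lo) & upper
    return (m >= lo) | upper  # wraps midnight


@dataclass
class AnalysisConfig:
    """All tunable constants of the pipeline, with the study defaults."""

    sampling_interval_min: int = 15
    night_window: tuple[str, str] = ("20:00", "04:00")   # nightly centroid fixes
    sleep_period: tuple[str, str] = ("21:00", "05:00")   # sleep metrics window
    day_window: tuple[str, str] = ("08:30", "17:30")     # interaction window
    onset_search: tuple[str, str] = ("19:00", "07:00")   # sleep onset/offset span

    # preprocessing
    max_gap_intervals: int = 4
    max_speed_mps: float = 3.0
    jitter_radius_m: float = 20.0

    # sleeping sites
    cluster_cut_m: float = 500.0
    cluster_linkage: str = "complete"
    min_night_fixes: int = 8

    # home ranges
    ud_level: float = 0.95
    ud_cell_m: float = 50.0
    ud_bandwidth_m: float | None = None   # None -> reference (Scott) rule

    # interactions
    merge_gap_min: float = 75.0
    cohesion_min_travel_m: float = 100.0
    cohesion_quantile: float = 0.80
    cohesion_fallback_m: float = 75.0   # used when no same-group dyads exist
    radius_bin_m: float = 100.0
    radius_max_m: float = 5000.0
    radius_min_obs: int = 50
    # free-travel window for movement-coordination metrics (radius inference
    # and site-specific post-sharing nulls): the return-to-roost leg is
    # excluded because travel then is destination-driven, not social
    foraging_window: tuple[str, str] = ("08:30", "14:30")
    min_step_m: float = 25.0   # below collar-noise scale, headings are meaningless

    # permutation engine
    n_permutations: int = 1000
    null_band: tuple[float, float] = (0.05, 0.95)
    day_start_hour: int = 12        # day-shift block boundary (keeps nights intact)
    min_shared_instances: int = 20  # site-specific null abstention threshold

    # sleep classification
    angle_threshold_deg: float = 5.0
    sleep_window_min: int = 5
    wake_bout_min: int = 2

    tz_offset_hours: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "sampling_interval_min max_gap_intervals max_speed_mps jitter_radius_m "
            "cluster_cut_m min_night_fixes ud_level ud_cell_m merge_gap_min "
            "cohesion_min_travel_m cohesion_quantile radius_bin_m radius_max_m "
            "radius_min_obs min_step_m n_permutations angle_threshold_deg "
            "sleep_window_min wake_bout_min min_shared_instances"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        lo, hi = self.null_band
        if not (0 < lo < hi < 1):
            raise ValueError("null_band must satisfy 0 < low < high < 1")
        for w in (self.night_window, self.sleep_period, self.day_window,
                  self.onset_search):
            parse_hhmm(w[0]), parse_hhmm(w[1])

    # -- persistence (flat key-value YAML) ----------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)

    @property
    def interval(self):
        import pandas as pd
        return pd.Timedelta(minutes=self.sampling_interval_min)

    @property
    def tzinfo(self):
        import datetime as _dt
        return _dt.timezone(_dt.timedelta(hours=self.tz_offset_hours))
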