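import numpy as np
import pandas as pd
import pytest

from nightshare.config import AnalysisConfig, in_window
from nightshare.interactions import (DyadSeries, Interaction, classify_cohesion,
                                     dyad_series, extract_interactions,
                                     front_behind_scores, within_group_threshold)
from nightshare.preprocess import OBSERVED, Trajectory

TZ = "+03:00"
IVL = pd.Timedelta(minutes=15)


def track(xy, ind="a", grp="GA", start=f"2021-01-01 09:00{TZ}"):
    xy = np.asarray(xy, float)
    return Trajectory(ind, grp, pd.Timestamp(start), IVL, xy,
                      np.full(len(xy), OBSERVED, np.int8))


def test_parallel_east_headings_zero_diff():
    a = track([(i * 100, 0) for i in range(6)], grp="GA")
    b = track([(i * 100, 500) for i in range(6)], grp="GB")
    ds = dyad_series(a, b, min_step_m=1)
    assert np.allclose(ds.heading_diff[1:], 0)
    assert np.allclose(ds.distance, 500)
    assert np.allclose(ds.step_diff[1:], 0)


def test_opposite_headings_180():
    a = track([(i * 100, 0) for i in range(6)], grp="GA")
    b = track([(1000 - i * 100, 200) for i in range(6)], grp="GB")
    ds = dyad_series(a, b, min_step_m=1)
    assert np.allclose(ds.heading_diff[1:], 180)


def test_small_steps_have_undefined_heading():
    a = track([(0, 0), (0.2, 0), (120, 0)], grp="GA")
    b = track([(0, 50), (50, 50), (100, 50)], grp="GB")
    ds = dyad_series(a, b, min_step_m=1)
    assert np.isnan(ds.heading_a[1]) and np.isnan(ds.heading_diff[1])
    assert np.isfinite(ds.heading_diff[2])


def test_dyad_series_matches_bruteforce():
    rng = np.random.default_rng(5)
    xa = np.cumsum(rng.normal(0, 80, (40, 2)), axis=0)
    xb = np.cumsum(rng.normal(0, 80, (40, 2)), axis=0)
    ds = dyad_series(track(xa, grp="GA"), track(xb, grp="GB"), min_step_m=1)
    for t in range(40):
        assert ds.distance[t] == pytest.approx(float(np.hypot(*(xa[t] - xb[t]))))
        if t > 0:
            ha = np.degrees(np.arctan2(*(xa[t] - xa[t - 1])[::-1]))
            hb = np.degrees(np.arctan2(*(xb[t] - xb[t - 1])[::-1]))
            d = abs(ha - hb) % 360
            d = 360 - d if d > 180 else d
            assert ds.heading_diff[t] == pytest.approx(d, abs=1e-9)
            sa = np.hypot(*(xa[t] - xa[t - 1]))
            sb = np.hypot(*(xb[t] - xb[t - 1]))
            assert ds.step_diff[t] == pytest.approx(abs(sa - sb))


def day_series(within, start=f"2021-01-01 00:00{TZ}"):
    """DyadSeries over full days whose distance encodes a within-radius mask."""
    n = len(within)
    dist = np.where(within, 100.0, 5000.0)
    times = pd.date_range(start, periods=n, freq=IVL)
    z = np.zeros((n, 2))
    return DyadSeries("GA", "GB", times, z, z, dist, *([np.zeros(n)] * 6))


def slot_of(hhmm):
    h, m = map(int, hhmm.split(":"))
    return h * 4 + m // 15


def test_sixty_minute_gap_merges():
    within = np.zeros(96, bool)
    within[slot_of("09:00"): slot_of("09:30") + 1] = True
    within[slot_of("10:30"): slot_of("11:00") + 1] = True   # 60-min gap
    out = extract_interactions(day_series(within), 600)
    assert len(out) == 1
    assert out[0].start.strftime("%H:%M") == "09:00"
    assert out[0].end.strftime("%H:%M") == "11:00"


def test_ninety_minute_gap_does_not_merge():
    within = np.zeros(96, bool)
    within[slot_of("09:00"): slot_of("09:30") + 1] = True
    within[slot_of("11:00"): slot_of("11:30") + 1] = True   # 90-min gap
    assert len(extract_interactions(day_series(within), 600)) == 2


def test_exact_75_minute_gap_does_not_merge():
    within = np.zeros(96, bool)
    within[slot_of("09:00")] = True
    within[slot_of("10:15")] = True
    assert len(extract_interactions(day_series(within), 600)) == 2


def test_overnight_continuity_splits_per_day():
    within = np.ones(192, bool)    # two full days continuously within radius
    out = extract_interactions(day_series(within), 600)
    assert len(out) == 2
    assert all(i.start.date() == i.end.date() for i in out)


def merge_oracle(slots, gap):
    """Brute-force interval merging: repeatedly join runs closer than gap."""
    runs = []
    for s in slots:
        if runs and s == runs[-1][1] + 1:
            runs[-1][1] = s
        else:
            runs.append([s, s])
    changed = True
    while changed:
        changed = False
        for i in range(len(runs) - 1):
            if runs[i + 1][0] - runs[i][1] < gap:
                runs[i][1] = runs[i + 1][1]
                del runs[i + 1]
                changed = True
                break
    return [tuple(r) for r in runs]


def test_extraction_matches_bruteforce_merge_oracle():
    rng = np.random.default_rng(9)
    day0, day1 = slot_of("08:30"), slot_of("17:30")
    for _ in range(300):
        within = rng.random(96) < 0.3
        out = extract_interactions(day_series(within), 600)
        day_slots = [s for s in np.flatnonzero(within) if day0 <= s <= day1]
        expect = merge_oracle(day_slots, gap=5)   # 75 min = 5 slots
        got = [(i.slots[0], i.slots[-1]) for i in out]
        assert got == expect


def test_preceded_by_shared_night_flag():
    within = np.zeros(96, bool)
    within[slot_of("10:00"): slot_of("11:00")] = True
    table = pd.DataFrame({"group_a": ["GA"], "group_b": ["GB"],
                          "night_date": [pd.Timestamp("2020-12-31").date()],
                          "same_site": [True]})
    out = extract_interactions(day_series(within), 600, shared_night_table=table)
    assert out[0].preceded_by_shared_night


def test_within_group_threshold_constant_and_uniform():
    a = track([(0, 0)] * 50 + [(i, 0) for i in range(50)], ind="a", grp="G")
    b = track([(0, 40)] * 50 + [(i, 40) for i in range(50)], ind="b", grp="G")
    assert within_group_threshold([a, b], 0.80, ("00:00", "23:45")) == pytest.approx(40.0)
    rng = np.random.default_rng(3)
    d = rng.uniform(0, 100, 10_000)
    a2 = track(np.zeros((10_000, 2)), ind="a", grp="G", start=f"2021-01-01 00:00{TZ}")
    b2 = track(np.c_[d, np.zeros(10_000)], ind="b", grp="G", start=f"2021-01-01 00:00{TZ}")
    thr = within_group_threshold([a2, b2], 0.80, ("00:00", "23:45"))
    assert abs(thr - 80.0) < 2.0


def test_within_group_threshold_requires_dyads():
    a = track([(0, 0)] * 10, ind="a", grp="G1")
    b = track([(0, 0)] * 10, ind="b", grp="G2")
    with pytest.raises(ValueError, match="threshold"):
        within_group_threshold([a, b])


def cohesion_case(xa, xb, thr, travel):
    ds = dyad_series(track(xa, grp="GA"), track(xb, grp="GB"), 1)
    it = Interaction("GA", "GB", ds.times[0], ds.times[-1], 1.0,
                     np.arange(len(ds)))
    return classify_cohesion(it, ds, thr, travel)


def test_cohesion_joint_travel_true_stationary_false():
    path = [(i * 100.0, 0) for i in range(6)]
    assert cohesion_case(path, [(x, y + 10) for x, y in path], 50, 100)
    still_a = [(0.0, 0.0)] * 6
    still_b = [(0.0, 10.0)] * 6
    assert not cohesion_case(still_a, still_b, 50, 100)


def test_cohesion_matches_exhaustive_run_enumeration():
    rng = np.random.default_rng(12)
    for _ in range(200):
        n = 12
        xa = np.cumsum(rng.normal(0, 60, (n, 2)), axis=0)
        xb = xa + rng.normal(0, 40, (n, 2))
        ds = dyad_series(track(xa, grp="GA"), track(xb, grp="GB"), 1)
        it = Interaction("GA", "GB", ds.times[0], ds.times[-1], 1.0, np.arange(n))
        got = classify_cohesion(it, ds, 60, 100)
        expect = False
        for i in range(n):
            for j in range(i + 1, n):
                if (ds.distance[i: j + 1] <= 60).all():
                    la = np.linalg.norm(np.diff(xa[i: j + 1], axis=0), axis=1).sum()
                    lb = np.linalg.norm(np.diff(xb[i: j + 1], axis=0), axis=1).sum()
                    if la >= 100 or lb >= 100:
                        expect = True
        assert got == expect


def test_front_behind_sign_and_antisymmetry():
    # a leads b along shared eastward travel
    a = track([(i * 100 + 50.0, 0) for i in range(6)], grp="GA")
    b = track([(i * 100.0, 0) for i in range(6)], grp="GB")
    ds = dyad_series(a, b, 1)
    scores, mean = front_behind_scores(ds)
    assert mean > 0
    # side by side: equidistant to the next centroid
    c = track([(i * 100.0, 50) for i in range(6)], grp="GC")
    d = track([(i * 100.0, -50) for i in range(6)], grp="GD")
    _, mid = front_behind_scores(dyad_series(c, d, 1))
    assert mid == pytest.approx(0.0, abs=1e-9)
    # swapping the dyad negates the scores exactly
    rng = np.random.default_rng(8)
    xa = np.cumsum(rng.normal(0, 70, (30, 2)), axis=0)
    xb = np.cumsum(rng.normal(0, 70, (30, 2)), axis=0)
    s1, _ = front_behind_scores(dyad_series(track(xa, grp="GA"), track(xb, grp="GB"), 1))
    s2, _ = front_behind_scores(dyad_series(track(xb, grp="GB"), track(xa, grp="GA"), 1))
    assert np.allclose(s1, -s2)
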