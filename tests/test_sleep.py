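import numpy as np
import pandas as pd
import pytest

from nightshare.config import AnalysisConfig
from nightshare.simulate import make_scenario, simulate_accel_frame, simulate_gps, simulate_sleep_labels
from nightshare.sleep import (build_effect_table, classify_minutes,
                              nightly_sleep_table, posture_angles, sleep_metrics,
                              summarize_sharing_effects, synchronization)

TZ = "+03:00"


def angle_frame(angles, start=f"2021-01-01 21:00{TZ}", ind="a"):
    n = len(angles)
    return pd.DataFrame({"individual_id": ind,
                         "timestamp": pd.date_range(start, periods=n, freq="1min"),
                         "angle_deg": np.asarray(angles, float)})


def states_from(labels, start=f"2021-01-01 21:00{TZ}", ind="a"):
    n = len(labels)
    return pd.DataFrame({"individual_id": ind,
                         "timestamp": pd.date_range(start, periods=n, freq="1min"),
                         "state": list(labels)})


def test_constant_orientation_is_sleep():
    st = classify_minutes(angle_frame([40.0] * 60))
    assert (st["state"] == "sleep").all()


def test_alternating_orientation_is_wake():
    st = classify_minutes(angle_frame([20.0, -20.0] * 30))
    assert (st["state"] == "wake").all()


def test_short_stable_runs_stay_wake():
    # 4 stable minutes (< 5-min window) bounded by big changes
    angles = [0, 50, 10, 10, 10, 10, 60, 0]
    st = classify_minutes(angle_frame(angles))
    assert (st["state"] == "wake").all()
    # 5 stable minutes qualify
    angles = [0, 50, 10, 10, 10, 10, 10, 60]
    st = classify_minutes(angle_frame(angles))
    assert list(st["state"][2:7]) == ["sleep"] * 5


def test_gaps_become_missing():
    f = angle_frame([40.0] * 10)
    f = pd.concat([f, angle_frame([40.0] * 10, start=f"2021-01-01 21:20{TZ}")],
                  ignore_index=True)
    st = classify_minutes(f)
    assert (st["state"][10:20] == "missing").all()
    assert len(st) == 30


def test_dead_sensor_burst_missing():
    from nightshare.io import AccelBurst
    z = np.zeros(32)
    g = np.full(32, 0.7)
    bursts = [AccelBurst("a", pd.Timestamp(f"2021-01-01 21:00{TZ}"), z, z, z),
              AccelBurst("a", pd.Timestamp(f"2021-01-01 21:01{TZ}"), g, g, g)]
    ang = posture_angles(bursts)
    assert np.isnan(ang["angle_deg"].iloc[0]) and np.isfinite(ang["angle_deg"].iloc[1])


def night_states(labels):
    """Label string covering exactly the 21:00-05:00 sleep period."""
    assert len(labels) == 480
    return states_from(labels)


def test_all_sleep_night_metrics():
    m = sleep_metrics(night_states(["sleep"] * 480))
    assert m["total_sleep_time_min"] == 480
    assert m["sleep_efficiency"] == 1.0
    assert m["fragmentation"] == 0.0


def test_fragmentation_hand_count():
    # 360 sleep minutes; wake bouts of 40, 30, 28 and 16 min (>= 2 min each)
    # plus six isolated 1-min wakes that must not count:
    # fragmentation = 4 bouts / 6 h sleep = 0.667 per hour
    lab = []
    for block, wake in zip([36] * 10, [40, 30, 28, 16, 1, 1, 1, 1, 1, 1]):
        lab += ["sleep"] * block + ["wake"] * wake
    lab += ["sleep"] * (480 - len(lab))
    counts = pd.Series(lab).value_counts()
    assert counts["sleep"] == 360 and counts["wake"] == 120
    m = sleep_metrics(night_states(lab))
    assert m["total_sleep_time_min"] == 360
    assert m["sleep_efficiency"] == pytest.approx(0.75)
    assert m["fragmentation"] == pytest.approx(4 / 6, abs=1e-9)


def test_wake_bout_length_boundary():
    base = ["sleep"] * 100
    one = base + ["wake"] * 1 + ["sleep"] * 379
    two = base + ["wake"] * 2 + ["sleep"] * 378
    assert sleep_metrics(night_states(one))["fragmentation"] == 0.0
    assert sleep_metrics(night_states(two))["fragmentation"] > 0


def test_zero_sleep_fragmentation_missing():
    m = sleep_metrics(night_states(["wake"] * 480))
    assert np.isnan(m["fragmentation"])
    assert m["total_sleep_time_min"] == 0


def test_undersampled_night_unusable():
    st = night_states(["sleep"] * 480)
    st.loc[st.index[:300], "state"] = "missing"
    assert sleep_metrics(st) is None


def test_onset_offset_bracket_sleep_runs():
    labels = ["wake"] * 50 + ["sleep"] * 400 + ["wake"] * 270
    st = states_from(labels, start=f"2021-01-01 19:00{TZ}")
    m = sleep_metrics(st)
    assert m["onset"] == pd.Timestamp(f"2021-01-01 19:50{TZ}")
    assert m["offset"] == pd.Timestamp(f"2021-01-02 02:29{TZ}")


def test_synchronization_extremes_and_independence():
    a = states_from(["sleep", "wake"] * 240)
    assert synchronization(a, a) == 1.0
    b = states_from(["wake", "sleep"] * 240, ind="b")
    assert synchronization(a, b) == 0.0
    rng = np.random.default_rng(17)
    n = 480
    sa = np.where(rng.random(n) < 0.8, "sleep", "wake")
    sb = np.where(rng.random(n) < 0.8, "sleep", "wake")
    score = synchronization(states_from(sa), states_from(sb, ind="b"))
    assert abs(score - 0.68) < 0.03      # p^2 + (1-p)^2 at p = 0.8
    # symmetric, and invariant to relabelling both series
    assert score == synchronization(states_from(sb), states_from(sa, ind="b"))
    flip = {"sleep": "wake", "wake": "sleep"}
    score2 = synchronization(states_from([flip[s] for s in sa]),
                             states_from([flip[s] for s in sb], ind="b"))
    assert score2 == score


def test_sync_missing_handling():
    a = states_from(["sleep"] * 10)
    b = states_from(["missing"] * 10, ind="b")
    assert np.isnan(synchronization(a, b))


def test_tst_monotone_in_angle_threshold():
    cfg, _ = make_scenario("sleep_disruption", seed=6, n_days=2,
                           n_groups=2, individuals_per_group=1)
    _, truth = simulate_gps(cfg)
    labels = simulate_sleep_labels(truth, cfg)
    frame = simulate_accel_frame(labels, cfg)
    tsts = []
    for thr in (2.0, 5.0, 10.0):
        st = classify_minutes(frame, angle_threshold_deg=thr)
        tsts.append((st["state"] == "sleep").sum())
    assert tsts[0] <= tsts[1] <= tsts[2]


@pytest.fixture(scope="module")
def disruption_run():
    config = AnalysisConfig()
    cfg, _ = make_scenario("sleep_disruption", seed=11, n_days=25)
    gps, truth = simulate_gps(cfg)
    labels = simulate_sleep_labels(truth, cfg)
    states = classify_minutes(simulate_accel_frame(labels, cfg))
    sn = nightly_sleep_table(states, config)
    rec = truth.night_sites.rename(columns={})
    # truth-based night records at the individual level
    rows = []
    for _, r in truth.night_sites.iterrows():
        if r["night_index"] < 0:
            continue
        for ind in cfg.individual_ids[r["group_id"]]:
            rows.append({"individual_id": ind, "group_id": r["group_id"],
                         "night_date": r["night_date"], "site_id": r["site_id"],
                         "shared": r["shared"]})
    night_records = pd.DataFrame(rows)
    eff, dyads = build_effect_table(sn, night_records, states, config)
    return cfg, truth, sn, eff, dyads


def test_effect_table_complete_and_truthful(disruption_run):
    cfg, truth, sn, eff, dyads = disruption_run
    assert {"individual_id", "group_id", "night_date", "site_id", "shared",
            "total_sleep_time_min", "sleep_efficiency",
            "fragmentation"}.issubset(eff.columns)
    # shared flags agree with the simulator truth
    tr = truth.night_sites.set_index(["group_id", "night_index"])["shared"]
    t0 = pd.Timestamp(cfg.start_date)
    for _, r in eff.sample(30, random_state=1).iterrows():
        night = (pd.Timestamp(r["night_date"]) - t0).days
        assert r["shared"] == tr.get((r["group_id"], night))
    # only usable nights produce records
    assert eff["total_sleep_time_min"].notna().all()
    # dyad table only pairs individuals across groups
    g = eff.groupby("individual_id")["group_id"].first()
    assert (dyads.apply(lambda r: g[r["individual_a"]] != g[r["individual_b"]],
                        axis=1)).all()


def test_contrast_zero_when_groups_identical():
    df = pd.DataFrame({
        "individual_id": ["i1"] * 10 + ["i2"] * 10,
        "shared": ([True] * 5 + [False] * 5) * 2,
        "total_sleep_time_min": [400, 410, 420, 430, 440] * 4,
        "sleep_efficiency": [0.8] * 20,
        "fragmentation": [1.0] * 20})
    con = summarize_sharing_effects(df, n_boot=200, seed=0)
    tst = con[con["metric"] == "total_sleep_time_min"].iloc[0]
    assert tst["difference"] == pytest.approx(0.0)
    assert tst["ci_lo"] <= 0 <= tst["ci_hi"]


def test_contrast_antisymmetric_under_flag_swap(disruption_run):
    *_, eff, _ = disruption_run
    con1 = summarize_sharing_effects(eff, n_boot=50, seed=2)
    swapped = eff.assign(shared=~eff["shared"].astype(bool))
    con2 = summarize_sharing_effects(swapped, n_boot=50, seed=2)
    assert np.allclose(con1["difference"], -con2["difference"], equal_nan=True)


def test_disruption_effect_directions(disruption_run):
    *_, eff, dyads = disruption_run
    con = summarize_sharing_effects(eff, n_boot=200, seed=3)
    tst = con[con["metric"] == "total_sleep_time_min"].iloc[0]
    frag = con[con["metric"] == "fragmentation"].iloc[0]
    assert tst["difference"] < 0
    assert frag["difference"] > 0
    sync = dyads.groupby("same_site")["synchronization"].mean()
    assert sync.get(True, np.nan) > sync.get(False, np.nan)
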