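"""Recovery and calibration experiments on synthetic data.

Each function simulates datasets under a named scenario, runs the relevant
pipeline stage, and reports how well the known ground truth is recovered:
type-I error of the day-shift null, power against post-sharing attraction,
response-radius recovery, sleeping-site recovery, sharing-test calibration,
sleep-classifier accuracy, and the sign/size of the sharing effect on sleep.
They back both the acceptance test-suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .interactions import infer_response_radius
from .permutation import build_null, make_metric, post_sharing_null, sharing_null
from .preprocess import clean_individual
from .simulate import make_scenario, simulate_accel_frame, simulate_gps, simulate_sleep_labels
from .sites import assign_to_sites, cluster_sites, flag_shared_nights, nightly_centroids
from .sleep import (build_effect_table, classify_minutes, nightly_sleep_table,
                    summarize_sharing_effects)

__all__ = [
    "group_tracks", "type_i_error_rate", "attraction_power", "radius_recovery",
    "null_radius_zero_rate", "site_recovery", "sharing_calibration",
    "forced_sharing_significance", "post_sharing_power",
    "classifier_accuracy", "sleep_effect_recovery",
]


def group_tracks(gps: pd.DataFrame, config: AnalysisConfig):
    trajs = clean_individual(gps, config)
    return {t.group_id: t for t in trajs}, trajs


def type_i_error_rate(n_datasets: int = 100, n_perm: int = 200,
                      seed: int = 0, config: AnalysisConfig | None = None) -> float:
    """Rejection rate of the mean-distance day-shift test on independent
    groups at the 90% inter-quantile band (nominal level 0.10)."""
    config = config or AnalysisConfig()
    fn = make_metric("mean_distance", config)
    rej = 0
    for i in range(n_datasets):
        cfg, _ = make_scenario("null_independent", seed=seed + 1000 + i)
        gps, _ = simulate_gps(cfg)
        tracks, _ = group_tracks(gps, config)
        nd = build_null(tracks["G1"], tracks["G2"], fn, n_perm,
                        seed=seed + i, config=config)
        rej += nd.significant
    return rej / n_datasets


def attraction_power(n_seeds: int = 20, n_perm: int = 200, seed: int = 0,
                     config: AnalysisConfig | None = None) -> float:
    """Fraction of post-sharing-attraction datasets whose empirical mean
    dyadic distance falls below the null 5th percentile."""
    config = config or AnalysisConfig()
    fn = make_metric("mean_distance", config)
    hits = 0
    for i in range(1, n_seeds + 1):
        cfg, _ = make_scenario("attraction_after_sharing", seed=seed + i)
        gps, _ = simulate_gps(cfg)
        tracks, _ = group_tracks(gps, config)
        nd = build_null(tracks["G1"], tracks["G2"], fn, n_perm,
                        seed=seed + i, config=config)
        hits += nd.empirical < nd.band[0]
    return hits / n_seeds


def _recover_radius(scenario: str, seed: int, n_perm: int,
                    config: AnalysisConfig) -> float:
    cfg, _ = make_scenario(scenario, seed=seed)
    gps, _ = simulate_gps(cfg)
    tracks, _ = group_tracks(gps, config)
    rr = infer_response_radius([(tracks["G1"], tracks["G2"])], config,
                               n_perm=n_perm, seed=seed)
    return rr.radius_m


def radius_recovery(n_seeds: int = 20, n_perm: int = 200, seed: int = 0,
                    config: AnalysisConfig | None = None) -> list[float]:
    """Recovered response radii (true radius 600 m) across seeds."""
    config = config or AnalysisConfig()
    return [_recover_radius("radius_600", seed + i, n_perm, config)
            for i in range(1, n_seeds + 1)]


def null_radius_zero_rate(n_seeds: int = 20, n_perm: int = 200, seed: int = 0,
                          config: AnalysisConfig | None = None) -> float:
    """Fraction of independent-group datasets with inferred radius 0."""
    config = config or AnalysisConfig()
    radii = [_recover_radius("null_independent", seed + i, n_perm, config)
             for i in range(1, n_seeds + 1)]
    return float(np.mean([r == 0 for r in radii]))


def site_recovery(n_seeds: int = 10, n_days: int = 150, seed: int = 0,
                  config: AnalysisConfig | None = None) -> tuple[float, float]:
    """(fraction of seeds recovering every simulated site as one cluster,
    overall night-assignment accuracy) under the study-like 4-group layout."""
    config = config or AnalysisConfig()
    exact = 0
    correct = total = 0
    for i in range(1, n_seeds + 1):
        cfg, _ = make_scenario("sleep_disruption", seed=seed + i, n_days=n_days)
        gps, truth = simulate_gps(cfg)
        _, trajs = group_tracks(gps, config)
        cents = pd.concat([nightly_centroids(t, config.night_window,
                                             config.min_night_fixes)
                           for t in trajs], ignore_index=True)
        sites, rec = cluster_sites(cents, config.cluster_cut_m, config.cluster_linkage)
        used = truth.night_sites["site_id"].nunique()
        exact += (len(sites) == used == cfg.n_sites)
        tn = truth.night_sites.assign(night_date=lambda d: d["night_date"].astype(str))
        m = rec.assign(night_date=rec["night_date"].astype(str)).merge(
            tn, on=["group_id", "night_date"], suffixes=("_rec", "_true"))
        # a recovered assignment is correct when its cluster maps one-to-one
        # onto the true site of every night in it
        lut = (m.groupby("site_id_rec")["site_id_true"]
               .agg(lambda s: s.mode().iloc[0]))
        correct += int((m["site_id_true"] == m["site_id_rec"].map(lut)).sum())
        total += len(m)
    return exact / n_seeds, correct / total


def sharing_calibration(n_seeds: int = 20, n_perm: int = 500, seed: int = 0,
                        config: AnalysisConfig | None = None,
                        p_share: float = 0.0) -> float:
    """Fraction of datasets where the sleeping-site-choice test is (correctly)
    non-significant under independent site choice; with ``p_share=1`` the
    complement measures power against forced sharing."""
    config = config or AnalysisConfig()
    nonsig = 0
    for i in range(1, n_seeds + 1):
        cfg, _ = make_scenario("null_independent", seed=seed + i, p_share=p_share)
        gps, _ = simulate_gps(cfg)
        _, trajs = group_tracks(gps, config)
        cents = pd.concat([nightly_centroids(t, config.night_window,
                                             config.min_night_fixes)
                           for t in trajs], ignore_index=True)
        site_table, nights = cluster_sites(cents, config.cluster_cut_m,
                                           config.cluster_linkage)
        nights, _ = flag_shared_nights(nights)
        assigner = lambda rec: assign_to_sites(rec, site_table, config.cluster_cut_m)
        nd = sharing_null(nights[nights["group_id"] == "G1"],
                          nights[nights["group_id"] == "G2"],
                          assigner, n_perm, seed + i, config)
        nonsig += not nd.significant
    return nonsig / n_seeds


def forced_sharing_significance(n_seeds: int = 10, n_perm: int = 500,
                                seed: int = 0,
                                config: AnalysisConfig | None = None) -> float:
    return 1.0 - sharing_calibration(n_seeds, n_perm, seed, config, p_share=1.0)


def post_sharing_power(n_seeds: int = 12, n_perm: int = 200, seed: int = 0,
                       config: AnalysisConfig | None = None) -> float:
    """Fraction of attraction datasets where next-day mean distance after
    sharing the most-shared site is below the site-specific null band."""
    config = config or AnalysisConfig()
    fn = make_metric("mean_distance", config)
    hits = tries = 0
    for i in range(1, n_seeds + 1):
        cfg, _ = make_scenario("attraction_after_sharing", seed=seed + i)
        gps, _ = simulate_gps(cfg)
        tracks, trajs = group_tracks(gps, config)
        cents = pd.concat([nightly_centroids(t, config.night_window,
                                             config.min_night_fixes)
                           for t in trajs], ignore_index=True)
        site_table, nights = cluster_sites(cents, config.cluster_cut_m,
                                           config.cluster_linkage)
        nights, dyads = flag_shared_nights(nights)
        shared = dyads[dyads["same_site"]]["site_id"].value_counts()
        if not len(shared):
            continue
        na = nights[nights["group_id"] == "G1"].set_index("night_date")["site_id"]
        nb = nights[nights["group_id"] == "G2"].set_index("night_date")["site_id"]
        nd = post_sharing_null(tracks["G1"], tracks["G2"], na, nb,
                               shared.index[0], fn, n_perm, seed + i,
                               config.min_shared_instances, config)
        if nd.abstained:
            continue
        tries += 1
        hits += nd.empirical < nd.band[0]
    return hits / tries if tries else np.nan


def classifier_accuracy(n_seeds: int = 20, n_nights: int = 3, seed: int = 0,
                        config: AnalysisConfig | None = None,
                        sleep_angle_sd_deg: float | None = None) -> list[float]:
    """Minute-level sleep/wake accuracy against simulator truth, per seed.

    ``sleep_angle_sd_deg`` overrides the postural-stability noise so that a
    degradation sweep can verify the classifier fails gracefully.
    """
    config = config or AnalysisConfig()
    accs = []
    for i in range(1, n_seeds + 1):
        kw = {} if sleep_angle_sd_deg is None else \
            {"sleep_angle_sd_deg": sleep_angle_sd_deg}
        cfg, _ = make_scenario("sleep_disruption", seed=seed + i,
                               n_days=n_nights, **kw)
        _, truth = simulate_gps(cfg)
        labels = simulate_sleep_labels(truth, cfg)
        states = classify_minutes(simulate_accel_frame(labels, cfg),
                                  config.angle_threshold_deg,
                                  config.sleep_window_min)
        m = labels.rename(columns={"state": "truth"}).merge(
            states[["individual_id", "timestamp", "state"]],
            on=["individual_id", "timestamp"])
        m = m[m["state"] != "missing"]
        accs.append(float((m["truth"] == m["state"]).mean()))
    return accs


def sleep_effect_recovery(n_seeds: int = 20, n_days: int = 50, seed: int = 0,
                          n_boot: int = 300,
                          config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Shared-night contrasts per seed: TST difference with bootstrap CI,
    fragmentation difference, and cross-group synchronization difference."""
    config = config or AnalysisConfig()
    rows = []
    for i in range(1, n_seeds + 1):
        cfg, _ = make_scenario("sleep_disruption", seed=seed + i, n_days=n_days)
        gps, truth = simulate_gps(cfg)
        _, trajs = group_tracks(gps, config)
        cents = pd.concat([nightly_centroids(t, config.night_window,
                                             config.min_night_fixes)
                           for t in trajs], ignore_index=True)
        _, nights = cluster_sites(cents, config.cluster_cut_m,
                                  config.cluster_linkage)
        nights, _ = flag_shared_nights(nights)
        labels = simulate_sleep_labels(truth, cfg)
        states = classify_minutes(simulate_accel_frame(labels, cfg),
                                  config.angle_threshold_deg,
                                  config.sleep_window_min)
        sn = nightly_sleep_table(states, config)
        eff, dyads = build_effect_table(sn, nights, states, config)
        con = summarize_sharing_effects(eff, n_boot=n_boot, seed=seed + i)
        tst = con[con["metric"] == "total_sleep_time_min"].iloc[0]
        frag = con[con["metric"] == "fragmentation"].iloc[0]
        sync = dyads.groupby("same_site")["synchronization"].mean()
        rows.append({"seed": seed + i,
                     "tst_diff": tst["difference"],
                     "tst_ci_lo": tst["ci_lo"], "tst_ci_hi": tst["ci_hi"],
                     "frag_diff": frag["difference"],
                     "sync_diff": float(sync.get(True, np.nan)
                                        - sync.get(False, np.nan))})
    return pd.DataFrame(rows)
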