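"""End-to-end orchestration: raw fixes to null-model tables and a run report.

Stage order: preprocess -> sleeping sites -> home ranges -> response radius
-> interactions -> permutation nulls -> sleep metrics -> effect tables.
Each stage writes its CSV into the output directory; a manifest (config
snapshot, input digests, seed, per-stage row counts) is written last so a
run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .io import fixes_to_frame, get_logger, read_gps, write_table
from .preprocess import build_group_track, clean_individual
from .homerange import bhattacharyya_affinity, estimate_ud, home_range, overlap_proportion
from .sites import cluster_sites, flag_shared_nights, nightly_centroids
from .interactions import (classify_cohesion, dyad_series, extract_interactions,
                           front_behind_scores, infer_response_radius,
                           within_group_threshold)
from .permutation import METRIC_NAMES, build_null, make_metric, post_sharing_null, sharing_null
from .sleep import build_effect_table, classify_minutes, nightly_sleep_table, summarize_sharing_effects

__all__ = ["run_pipeline", "report"]

log = get_logger()


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _null_row(dyad, test, nd):
    return {"dyad": dyad, "test": test, "empirical": nd.empirical,
            "band_lo": nd.band[0], "band_hi": nd.band[1],
            "p_low": nd.p_low, "p_high": nd.p_high,
            "significant": nd.significant, "abstained": nd.abstained,
            "n_instances": nd.n_instances}


def run_pipeline(gps, accel=None, config: AnalysisConfig | None = None,
                 outdir: str | Path = "nightshare_run", seed: int = 0,
                 n_perm: int | None = None) -> Path:
    """Run every GPS stage (and the sleep stages when accelerometry is given).

    ``gps`` is a fix CSV path or a tidy fix DataFrame; ``accel`` a burst CSV
    path, a burst list, or a per-minute state frame.  Returns the output
    directory.  When the accelerometry input is missing the sleep stages are
    skipped and flagged in the manifest.
    """
    config = config or AnalysisConfig()
    n_perm = n_perm or config.n_permutations
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": seed,
                      "n_permutations": n_perm,
                      "config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in dataclasses.asdict(config).items()},
                      "inputs": {}, "rows": {}, "stages": []}

    # ---- ingest + preprocess
    if isinstance(gps, (str, Path)):
        manifest["inputs"]["gps"] = _digest(gps)
        gps = fixes_to_frame(read_gps(gps))
    trajs = clean_individual(gps, config)
    manifest["rows"]["individuals"] = len(trajs)
    by_group: dict[str, list] = {}
    for t in trajs:
        by_group.setdefault(t.group_id, []).append(t)
    tracks = {g: build_group_track(ms) for g, ms in sorted(by_group.items())}
    manifest["stages"].append("preprocess")

    # ---- sleeping sites
    cents = pd.concat([nightly_centroids(t, config.night_window, config.min_night_fixes)
                       for t in trajs], ignore_index=True)
    site_table, nights = cluster_sites(cents, config.cluster_cut_m, config.cluster_linkage)
    nights, dyad_nights = flag_shared_nights(nights)
    write_table(site_table, outdir / "sites.csv", "sites")
    write_table(nights, outdir / "nights.csv", "nights")
    dyad_nights.to_csv(outdir / "dyad_nights_gps.csv", index=False)
    manifest["rows"]["sites"] = len(site_table)
    manifest["rows"]["nights"] = len(nights)
    manifest["stages"].append("sites")

    # ---- home ranges
    hr_rows, uds, masks = [], {}, {}
    for g, tr in tracks.items():
        try:
            ud = estimate_ud(tr, config.ud_cell_m, config.ud_bandwidth_m)
        except ValueError as e:
            log.warning("home range for %s skipped: %s", g, e)
            continue
        uds[g] = ud
        masks[g], area = home_range(ud, config.ud_level)
        hr_rows.append({"group_id": g, "area_km2": area / 1e6})
    overlaps = []
    for a, b in itertools.combinations(sorted(uds), 2):
        ba = bhattacharyya_affinity(uds[a], uds[b])
        try:
            oa, ob = overlap_proportion(masks[a], masks[b])
        except ValueError:
            oa = ob = np.nan   # UD grids differ; BA regrids, masks do not
        overlaps.append({"group_a": a, "group_b": b, "bhattacharyya": ba,
                         "overlap_a_in_b": ob, "overlap_b_in_a": oa})
    pd.DataFrame(hr_rows).to_csv(outdir / "home_ranges.csv", index=False)
    pd.DataFrame(overlaps).to_csv(outdir / "home_range_overlap.csv", index=False)
    manifest["stages"].append("homerange")

    # ---- response radius (pooled over dyads)
    pairs = list(itertools.combinations(sorted(tracks), 2))
    try:
        rr = infer_response_radius([(tracks[a], tracks[b]) for a, b in pairs],
                                   config, n_perm=n_perm, seed=seed)
    except ValueError as e:
        log.warning("response-radius inference failed (%s); "
                    "using default 600 m", e)
        rr = None
    radius = config.radius_bin_m * 6 if rr is None or rr.radius_m <= 0 else rr.radius_m
    if rr is not None:
        pd.DataFrame({"bin_lo": rr.bin_edges[:-1], "empirical": rr.empirical,
                      "count": rr.counts, "null_lo": rr.null_lo,
                      "null_hi": rr.null_hi}).to_csv(outdir / "radius_bins.csv",
                                                     index=False)
    manifest["rows"]["response_radius_m"] = rr.radius_m if rr is not None else None
    manifest["stages"].append("radius")

    # ---- interactions
    try:
        thr = within_group_threshold(trajs, config.cohesion_quantile, config.day_window)
    except ValueError:
        log.warning("no same-group collared dyads; using configured fallback "
                    "cohesion threshold %.0f m", config.cohesion_fallback_m)
        thr = config.cohesion_fallback_m
    inter_rows = []
    for a, b in pairs:
        ds = dyad_series(tracks[a], tracks[b], config.min_step_m)
        if len(ds) == 0:
            continue
        for it in extract_interactions(ds, radius, config, dyad_nights):
            it.cohesive = classify_cohesion(it, ds, thr, config.cohesion_min_travel_m)
            _, it.front_behind_mean = front_behind_scores(ds, it.slots)
            inter_rows.append({"group_a": it.group_a, "group_b": it.group_b,
                               "start": it.start, "end": it.end,
                               "duration_h": it.duration_h, "cohesive": it.cohesive,
                               "preceded_by_shared_night": it.preceded_by_shared_night,
                               "front_behind_mean": it.front_behind_mean})
    inter = pd.DataFrame(inter_rows, columns=["group_a", "group_b", "start", "end",
                                              "duration_h", "cohesive",
                                              "preceded_by_shared_night",
                                              "front_behind_mean"])
    write_table(inter, outdir / "interactions.csv", "interactions")
    manifest["rows"]["interactions"] = len(inter)
    manifest["rows"]["cohesion_threshold_m"] = thr
    manifest["stages"].append("interactions")

    # ---- permutation nulls
    null_rows = []
    rng = np.random.default_rng(seed)
    for a, b in pairs:
        dyad = f"{a}-{b}"
        for name in METRIC_NAMES:
            fn = make_metric(name, config, radius_m=radius)
            nd = build_null(tracks[a], tracks[b], fn, n_perm,
                            int(rng.integers(2**31)), config)
            null_rows.append(_null_row(dyad, name, nd))
        na = nights[nights["group_id"] == a]
        nb_ = nights[nights["group_id"] == b]
        from .sites import assign_to_sites
        assigner = lambda rec: assign_to_sites(rec, site_table, config.cluster_cut_m)
        nd = sharing_null(na, nb_, assigner, n_perm, int(rng.integers(2**31)), config)
        null_rows.append(_null_row(dyad, "sharing", nd))
        # site-specific post-sharing nulls for sites this dyad ever shared
        shared_sites = (dyad_nights[(dyad_nights["same_site"])
                                    & (dyad_nights["group_a"] == a)
                                    & (dyad_nights["group_b"] == b)]["site_id"]
                        .dropna().unique())
        ns_a = na.dropna(subset=["site_id"]).set_index("night_date")["site_id"]
        ns_b = nb_.dropna(subset=["site_id"]).set_index("night_date")["site_id"]
        for sid in shared_sites:
            nd = post_sharing_null(tracks[a], tracks[b], ns_a, ns_b, sid,
                                   make_metric("mean_distance", config),
                                   n_perm, int(rng.integers(2**31)),
                                   config.min_shared_instances, config)
            null_rows.append(_null_row(dyad, f"post_sharing:{sid}", nd))
    pd.DataFrame(null_rows).to_csv(outdir / "null_tests.csv", index=False)
    manifest["rows"]["null_tests"] = len(null_rows)
    manifest["stages"].append("permutation")

    # ---- sleep
    if accel is None:
        manifest["stages"].append("sleep:skipped (no accelerometry input)")
        log.warning("no accelerometry input; sleep stage skipped")
    else:
        if isinstance(accel, (str, Path)):
            manifest["inputs"]["accel"] = _digest(accel)
            from .io import read_accel
            accel = read_accel(accel)
        states = (accel if isinstance(accel, pd.DataFrame) and "state" in accel.columns
                  else classify_minutes(accel, config.angle_threshold_deg,
                                        config.sleep_window_min))
        sn = nightly_sleep_table(states, config)
        eff, dyad_eff = build_effect_table(sn, nights, states, config)
        eff.to_csv(outdir / "sleep_nights.csv", index=False)
        dyad_eff.to_csv(outdir / "sleep_dyad_nights.csv", index=False)
        contrasts = summarize_sharing_effects(eff, seed=seed) if eff["shared"].nunique() == 2 \
            else pd.DataFrame()
        contrasts.to_csv(outdir / "sleep_contrasts.csv", index=False)
        manifest["rows"]["sleep_nights"] = len(eff)
        manifest["rows"]["sleep_dyad_nights"] = len(dyad_eff)
        manifest["stages"].append("sleep")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def report(outdir: str | Path, plots: bool = True) -> str:
    """Text summary of a pipeline run (written to ``report.txt``).

    Tables: per-dyad null-model outcomes for the five attraction metrics and
    the sharing test (abstentions shown as such), interaction counts split by
    preceding-night sharing, and the sleep contrasts.
    """
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    lines = [f"nightshare run report (v{manifest['version']}, seed {manifest['seed']})",
             "=" * 60, ""]
    nulls = pd.read_csv(outdir / "null_tests.csv")
    lines.append("Permutation null models (empirical vs 90% null band):")
    for _, r in nulls.iterrows():
        if r["abstained"] and not np.isfinite(r["empirical"]):
            n_inst = 0 if pd.isna(r["n_instances"]) else int(r["n_instances"])
            lines.append(f"  {r['dyad']:<12} {r['test']:<22} ABSTAINED "
                         f"(instances={n_inst})")
        else:
            flag = "*" if r["significant"] else " "
            lines.append(f"  {r['dyad']:<12} {r['test']:<22} emp={r['empirical']:.3g} "
                         f"band=[{r['band_lo']:.3g}, {r['band_hi']:.3g}] "
                         f"p_low={r['p_low']:.3g} p_high={r['p_high']:.3g} {flag}")
    lines.append("")
    inter = pd.read_csv(outdir / "interactions.csv")
    n_after = int(inter["preceded_by_shared_night"].sum()) if len(inter) else 0
    lines.append(f"Interactions: {len(inter)} total; {n_after} on days after a "
                 f"shared night; {int(inter['cohesive'].sum()) if len(inter) else 0} cohesive.")
    rr_path = outdir / "radius_bins.csv"
    rad = manifest["rows"]["response_radius_m"]
    if rr_path.exists() and rad is not None:
        rr = pd.read_csv(rr_path)
        lines.append(f"Response radius: {rad:.0f} m "
                     f"({int((rr['count'] > 0).sum())} occupied distance bins).")
    else:
        lines.append("Response radius: not inferable (too little dyadic data).")
    sleep_path = outdir / "sleep_contrasts.csv"
    if sleep_path.exists():
        con = pd.read_csv(sleep_path)
        if len(con):
            lines.append("")
            lines.append("Sleep contrasts (shared - unshared nights, 95% bootstrap CI):")
            for _, r in con.iterrows():
                lines.append(f"  {r['metric']:<22} {r['difference']:+.3f} "
                             f"[{r['ci_lo']:+.3f}, {r['ci_hi']:+.3f}]")
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text)
    if plots and rr_path.exists():
        try:
            _plots(outdir, nulls)
        except Exception as e:       # plotting must never sink a run
            log.warning("report plots skipped: %s", e)
    return text


def _plots(outdir: Path, nulls: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    rr = pd.read_csv(outdir / "radius_bins.csv")
    fig, ax = plt.subplots(figsize=(7, 4))
    mid = rr["bin_lo"] + np.diff(np.r_[rr["bin_lo"], rr["bin_lo"].iloc[-1] + 100]) / 2
    ax.fill_between(mid, rr["null_lo"], rr["null_hi"], alpha=0.3, label="90% null band")
    ax.plot(mid, rr["empirical"], "o-", ms=3, label="empirical")
    ax.set_xlabel("intergroup distance bin (m)")
    ax.set_ylabel("mean heading difference (deg)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "radius_bins.png", dpi=120)
    plt.close(fig)
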