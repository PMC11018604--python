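"""End-to-end orchestration: simulate -> preprocess -> classify -> report.

Every stage draws its randomness from a generator derived from the master
seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .decoding import FEATURE_OEPC, FEATURE_RHO, decode_profile
from .detection import classify_session
from .events import (annotate_speed_drops, identify_ra_cells,
                     period_mean_activity, reward_proximal_bins)
from .io import read_session, write_session
from .synthetic import generate_session
from .trajectory import (assign_bins, flag_hd_outliers, flag_offtrack,
                         process_trajectory)
from .utils import spawn_rng

log = logging.getLogger("oepc")


def preprocess_session(bundle, config: PipelineConfig):
    """Rebuild trajectory + bouts (+ masks) from a raw session bundle."""
    tdf = bundle["trajectory"]
    sess = config.session
    hd = tdf["hd"].to_numpy(float) if "hd" in tdf and \
        np.isfinite(tdf["hd"]).any() else None
    traj, bouts = process_trajectory(
        tdf["t"].to_numpy(float),
        tdf[["x", "y"]].to_numpy(float), hd, sess,
        labels=bundle["labels"],
        excluded_ranges=bundle.get("excluded_ranges", ()),
        smooth_window=config.analysis.speed_smooth_window,
        lap_tolerance=config.analysis.lap_tolerance)
    flag_offtrack(bouts, traj, config.analysis.exclusion_sd)
    flag_hd_outliers(bouts, traj, config.analysis.exclusion_sd)
    return traj, bouts


def run_pipeline(config: PipelineConfig, outdir, simulate: bool = True,
                 session_dir=None, decode: bool = True) -> dict:
    """Run every stage and write all outputs under ``outdir``.

    Returns the session report (also written as report.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ana = config.analysis
    if simulate:
        log.info("simulating session (seed=%d)", config.seed)
        traj, bouts, activity, truth = generate_session(config.session,
                                                        config.population)
        write_session(outdir / "session", config, traj, bouts, activity,
                      truth)
        flag_offtrack(bouts, traj, ana.exclusion_sd)
        flag_hd_outliers(bouts, traj, ana.exclusion_sd)
    else:
        bundle = read_session(session_dir)
        if bundle["activity"] is None:
            raise FileNotFoundError(
                f"missing activity file: {Path(session_dir) / 'activity.csv'}")
        activity = bundle["activity"]
        truth = None
        traj, bouts = preprocess_session(bundle, config)
    if activity.shape[1] != traj.n_frames:
        raise ValueError("activity and trajectory disagree on frame count")

    log.info("classifying %d cells", activity.shape[0])
    rng = spawn_rng(ana.seed, "classify")
    cls = classify_session(activity, traj, bouts,
                           n_si_shuffles=ana.n_si_shuffles,
                           n_bout_shuffles=ana.n_bout_shuffles,
                           z_threshold=ana.si_z_threshold,
                           min_activity=ana.min_activity,
                           criterion=ana.bootstrap_criterion,
                           min_bouts=ana.min_bouts,
                           field_threshold=ana.field_threshold, rng=rng)

    # reward-associated cells, oePC-overlap excluded
    from .spatial import tuning_curve
    reward_bin = int(assign_bins([config.session.reward_angle],
                                 config.session.reward_angle, ana.n_bins)[0])
    ra = []
    for ci in range(activity.shape[0]):
        vec = tuning_curve(activity[ci], traj, ci).mean_rate_per_bin
        ra.append(identify_ra_cells(vec, reward_bin, ana.reward_window_bins,
                                    ana.ra_sd))
    cls["is_ra_raw"] = ra
    cls["is_ra"] = cls["is_ra_raw"] & ~cls["is_oepc"]

    events, baseline = annotate_speed_drops(
        traj, bouts, config.session.reward_angle,
        enter=ana.speed_drop_enter, exit=ana.speed_drop_exit)
    period_rows = []
    for ci in range(activity.shape[0]):
        means = period_mean_activity(activity[ci], events, baseline)
        means["cell_id"] = ci
        period_rows.append(means)
    periods = pd.DataFrame(period_rows)

    with open(outdir / "classification.csv", "w") as fh:
        fh.write(f"# seed={config.seed}\n")
        cls.to_csv(fh, index=False)
    with open(outdir / "period_activity.csv", "w") as fh:
        fh.write(f"# seed={config.seed}\n")
        periods.to_csv(fh, index=False)

    decode_df = pd.DataFrame()
    if decode and cls["is_oepc"].any():
        frames_dec = []
        drng = spawn_rng(ana.seed, "decode")
        for oid in sorted(cls.loc[cls.is_oepc, "object_id"].unique()):
            cells = cls.loc[cls.is_oepc & (cls.object_id == oid),
                            "cell_id"].tolist()
            obj_bin = int(assign_bins([config.session.object_angles[int(oid)]],
                                      config.session.reward_angle,
                                      ana.n_bins)[0])
            for fs in (FEATURE_OEPC, FEATURE_RHO):
                for excl in (False, True):
                    frames_dec.append(decode_profile(
                        activity, traj, bouts, int(oid), obj_bin,
                        cell_ids=cells, feature_set=fs,
                        exclude_offtrack=excl,
                        n_perm=ana.n_decode_permutations, rng=drng,
                        min_bouts=ana.min_bouts))
        decode_df = pd.concat(frames_dec, ignore_index=True)
        with open(outdir / "decoding.csv", "w") as fh:
            fh.write(f"# seed={config.seed}\n")
            decode_df.to_csv(fh, index=False)

    report = {
        "seed": config.seed,
        "n_cells": int(activity.shape[0]),
        "n_laps": int(len(traj.lap_ids)),
        "n_bouts": len(bouts),
        "n_place_cells": int(cls["is_place_cell"].sum()),
        "n_oepc": int(cls["is_oepc"].sum()),
        "n_ra": int(cls["is_ra"].sum()),
        "oepc_di_median": float(cls.loc[cls.is_oepc, "di"].median())
        if cls["is_oepc"].any() else None,
        "n_speed_drop_events": len(events),
    }
    if truth is not None:
        roles = truth.cells["role"]
        true_oepc = set(truth.cells.loc[roles == "oePC", "cell_id"])
        found = set(cls.loc[cls.is_oepc, "cell_id"])
        report["n_true_oepc"] = len(true_oepc)
        report["oepc_sensitivity"] = (len(true_oepc & found) / len(true_oepc)
                                      if true_oepc else None)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
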