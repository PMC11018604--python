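"""Identification of object exploration-dependent place cells (oePCs).

For each cell x object with at least three exploration and three
non-exploration bouts, the maximum binned activity is computed per bout
and the difference in means between the two behaviors is compared with a
1000-fold bout-label shuffle: the cell passes if the observed difference
exceeds 99.0% of the chance differences. A cell is an oePC if it passes
for some object, its spatial-information z-score over the exploration laps
of that object is >= 1.65, and its session-maximum inferred activity is at
least 2 arb. units. The Difference Index

    DI = (max(r_exp) - max(r_nonexp)) / (max(r_exp) + max(r_nonexp))

contrasts peak lap-average activity over the three object-centered bins
between the two behaviors. After off-track / head-direction exclusion, a
two-sided Mann-Whitney U test on frame-level activity rechecks that
exploration activity remains higher (retention at p <= 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .spatial import (SpatialTuningCurve, si_zscore, classify_place_cell,
                      detect_place_fields, compute_com, tuning_curve)
from .trajectory import EXPLORATION, NON_EXPLORATION, PolarTrajectory
from .utils import wrap_angle


@dataclass
class BoutActivitySummary:
    """Observed bout-maximum statistics for one cell x object."""

    cell_id: int
    object_id: int
    expl_max: np.ndarray
    nonexpl_max: np.ndarray
    observed_diff: float
    null_diffs: np.ndarray | None = None
    percentile: float = np.nan

    @property
    def eligible(self) -> bool:
        """Minimum of three bouts of each label."""
        return len(self.expl_max) >= 3 and len(self.nonexpl_max) >= 3


def bout_max_activity(activity: np.ndarray, traj: PolarTrajectory,
                      bouts, object_id: int, cell_id: int = 0,
                      exclude_offtrack: bool = False,
                      exclude_hd_outliers: bool = False) -> BoutActivitySummary:
    """Per-bout maximum binned activity for one cell and object.

    For each bout, activity is averaged per angular bin over the bout's
    frames (optionally after removing masked frames) and the maximum over
    the bout's bins taken. A bout whose frames are entirely masked is
    dropped.
    """
    activity = np.asarray(activity, dtype=float)
    expl, nonexpl = [], []
    for b in bouts:
        if b.object_id != object_id or b.label not in (EXPLORATION,
                                                       NON_EXPLORATION):
            continue
        f = b.valid_frames(traj, exclude_offtrack=exclude_offtrack,
                           exclude_hd_outliers=exclude_hd_outliers)
        if len(f) == 0:
            continue
        binned = pd.Series(activity[f]).groupby(traj.bin[f]).mean()
        m = float(binned.max())
        (expl if b.label == EXPLORATION else nonexpl).append(m)
    expl = np.asarray(expl, dtype=float)
    nonexpl = np.asarray(nonexpl, dtype=float)
    diff = (expl.mean() - nonexpl.mean()
            if len(expl) and len(nonexpl) else np.nan)
    return BoutActivitySummary(cell_id=cell_id, object_id=object_id,
                               expl_max=expl, nonexpl_max=nonexpl,
                               observed_diff=diff)


# ---------------------------------------------------------------------------
# the label-shuffle test


def shuffle_null_diffs(expl_max, nonexpl_max, n_shuffles: int = 1000,
                       rng=None) -> np.ndarray:
    """Monte-Carlo null: differences of means under random label shuffles.

    Each shuffle randomly permutes the pooled bout maxima and reassigns
    the first n_expl to the exploration group, preserving group sizes.
    """
    rng = np.random.default_rng(rng)
    pooled = np.concatenate([expl_max, nonexpl_max])
    k = len(expl_max)
    perms = rng.permuted(np.tile(pooled, (n_shuffles, 1)), axis=1)
    return perms[:, :k].mean(axis=1) - perms[:, k:].mean(axis=1)


def enumerate_null_diffs(expl_max, nonexpl_max) -> np.ndarray:
    """Exact null: difference of means for every label arrangement.

    Enumerates all C(n, n_expl) assignments of the pooled maxima to the
    exploration group. Intended as an oracle for small bout counts.
    """
    pooled = np.concatenate([expl_max, nonexpl_max])
    n, k = len(pooled), len(expl_max)
    total = pooled.sum()
    diffs = []
    for idx in combinations(range(n), k):
        s = pooled[list(idx)].sum()
        diffs.append(s / k - (total - s) / (n - k))
    return np.asarray(diffs)


def bootstrap_test(summary: BoutActivitySummary, n_shuffles: int = 1000,
                   rng=None, criterion: float = 0.99):
    """Label-shuffle significance of the observed bout-max difference.

    The percentile is the fraction of null differences strictly below the
    observed one; the cell passes iff that fraction is >= ``criterion``
    (the observed difference exceeds 99.0% of the chance values). Ties in
    the null count against the cell, so a degenerate null (all bout maxima
    identical) automatically fails. The summary is updated in place and
    (percentile, passed) returned.
    """
    if not summary.eligible:
        raise ValueError("summary ineligible: need >= 3 bouts per label")
    null = shuffle_null_diffs(summary.expl_max, summary.nonexpl_max,
                              n_shuffles, rng)
    percentile = float(np.mean(null < summary.observed_diff))
    summary.null_diffs = null
    summary.percentile = percentile
    return percentile, percentile >= criterion


def classify_oepc(bootstrap_pass: bool, si_z_expl: float,
                  max_activity: float, z_threshold: float = 1.65,
                  min_activity: float = 2.0):
    """Conjunction of the three oePC criteria, with reason codes.

    oePC iff the bout-shuffle test passed, the SI z-score over exploration
    laps is >= ``z_threshold``, and the cell's session-maximum inferred
    activity is >= ``min_activity`` arb. units.
    """
    reasons = []
    if not bootstrap_pass:
        reasons.append("bout-shuffle test failed")
    if not classify_place_cell(si_z_expl, z_threshold):
        reasons.append("SI not significant in exploration laps")
    if not (np.isfinite(max_activity) and max_activity >= min_activity):
        reasons.append("low-activity exclusion")
    return len(reasons) == 0, reasons


def difference_index(expl_vec, nonexpl_vec, object_bin: int) -> float:
    """Normalized exploration/non-exploration contrast at the object.

    Uses the maxima of the two lap-average bin vectors over the three
    bins centered on the object bin (circular). NaN if both maxima are 0.
    """
    e = np.nan_to_num(np.asarray(expl_vec, dtype=float))
    ne = np.nan_to_num(np.asarray(nonexpl_vec, dtype=float))
    n = len(e)
    sel = [(object_bin - 1) % n, object_bin, (object_bin + 1) % n]
    me, mn = e[sel].max(), ne[sel].max()
    if me + mn <= 0:
        return np.nan
    return float((me - mn) / (me + mn))


def lap_average_maps(expl_mat: np.ndarray, nonexpl_mat: np.ndarray,
                     coms: np.ndarray):
    """Normalized, COM-sorted exploration / non-exploration maps.

    Each cell's pair of 24-bin vectors is normalized by its exploration
    maximum; rows with exploration maximum <= 0 are dropped with a
    warning; rows are stably sorted by COM; the difference map is
    exploration minus non-exploration.

    Returns (expl, nonexpl, diff, row_order) where row_order indexes the
    retained input rows in sorted order.
    """
    expl_mat = np.nan_to_num(np.asarray(expl_mat, dtype=float))
    nonexpl_mat = np.nan_to_num(np.asarray(nonexpl_mat, dtype=float))
    coms = np.asarray(coms, dtype=float)
    peak = expl_mat.max(axis=1)
    keep = peak > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} cell(s) silent in exploration "
                      "laps dropped from the map")
    idx = np.where(keep)[0]
    order = idx[np.argsort(coms[idx], kind="stable")]
    e = expl_mat[order] / peak[order, None]
    ne = nonexpl_mat[order] / peak[order, None]
    return e, ne, e - ne, order


def postexclusion_recheck(activity: np.ndarray, traj: PolarTrajectory,
                          bouts, object_id: int,
                          exclude_offtrack: bool = True,
                          exclude_hd_outliers: bool = False,
                          alpha: float = 0.05):
    """Mann-Whitney recheck of exploration > non-exploration activity.

    Frame-level activity in exploration vs non-exploration bouts of the
    object is compared with a two-sided rank-sum test after removing the
    masked frames. Returns (p_value, retained); a cell whose exploration
    frames are entirely masked is dropped (NaN, False).
    """
    activity = np.asarray(activity, dtype=float)
    expl_f, nonexpl_f = [], []
    for b in bouts:
        if b.object_id != object_id:
            continue
        if b.label == EXPLORATION:
            expl_f.append(b.valid_frames(traj, exclude_offtrack,
                                         exclude_hd_outliers))
        elif b.label == NON_EXPLORATION:
            nonexpl_f.append(b.frames(traj))
    expl_f = np.concatenate(expl_f) if expl_f else np.array([], int)
    nonexpl_f = np.concatenate(nonexpl_f) if nonexpl_f else np.array([], int)
    if len(expl_f) == 0 or len(nonexpl_f) == 0:
        return np.nan, False
    a, b_ = activity[expl_f], activity[nonexpl_f]
    if np.all(a == a[0]) and np.all(b_ == a[0]):
        return 1.0, False
    p = float(stats.mannwhitneyu(a, b_, alternative="two-sided").pvalue)
    return p, p <= alpha


# ---------------------------------------------------------------------------
# session-level driver


def classify_session(activity: np.ndarray, traj: PolarTrajectory, bouts,
                     n_si_shuffles: int = 100, n_bout_shuffles: int = 1000,
                     z_threshold: float = 1.65, min_activity: float = 2.0,
                     criterion: float = 0.99, min_bouts: int = 3,
                     field_threshold: float = 0.2, rng=None,
                     recheck: bool = True) -> pd.DataFrame:
    """Classify every cell of a session; one row per cell.

    Columns: cell_id, max_activity, si, si_z, is_place_cell, n_fields,
    com, is_oepc, object_id (best qualifying object, else -1), percentile,
    di, si_expl, si_z_expl, recheck_p, retained, reasons.
    """
    rng = np.random.default_rng(rng)
    activity = np.asarray(activity, dtype=float)
    if activity.ndim != 2 or activity.shape[1] != traj.n_frames:
        raise ValueError("activity must be cells x frames, aligned to the "
                         "trajectory")
    object_ids = sorted({b.object_id for b in bouts})
    # exploration/non-exploration laps per object
    expl_laps = {o: sorted({b.lap_id for b in bouts
                            if b.object_id == o and b.label == EXPLORATION})
                 for o in object_ids}
    nonexpl_laps = {o: sorted({b.lap_id for b in bouts
                               if b.object_id == o
                               and b.label == NON_EXPLORATION})
                    for o in object_ids}
    object_bin = {}
    for o in object_ids:
        bs = [b for b in bouts if b.object_id == o]
        mid_frames = [b.frames(traj)[len(b.frames(traj)) // 2] for b in bs
                      if len(b.frames(traj))]
        object_bin[o] = int(np.median([traj.bin[f] for f in mid_frames]))

    rows = []
    for ci in range(activity.shape[0]):
        a = activity[ci]
        max_act = float(a.max())
        si, z, _ = si_zscore(a, traj, n_si_shuffles, rng)
        curve = tuning_curve(a, traj, ci)
        vec = np.nan_to_num(curve.mean_rate_per_bin)
        is_pc = classify_place_cell(z, z_threshold)
        fields = detect_place_fields(vec, traj.reward_angle, field_threshold) \
            if vec.max() > 0 else []
        com = compute_com(vec, reward_angle=traj.reward_angle) \
            if (vec > 0).any() else np.nan
        best = {"object_id": -1, "percentile": np.nan, "passed": False,
                "di": np.nan, "si_expl": np.nan, "si_z_expl": np.nan,
                "recheck_p": np.nan, "retained": False}
        reasons: list = []
        for o in object_ids:
            summary = bout_max_activity(a, traj, bouts, o, ci)
            if not (len(summary.expl_max) >= min_bouts
                    and len(summary.nonexpl_max) >= min_bouts):
                continue
            pct, passed = bootstrap_test(summary, n_bout_shuffles, rng,
                                         criterion)
            if not (np.isnan(best["percentile"]) or pct > best["percentile"]):
                continue
            if expl_laps[o]:
                si_e, z_e, _ = si_zscore(a, traj, n_si_shuffles, rng,
                                         lap_subset=expl_laps[o])
            else:
                si_e, z_e = np.nan, np.nan
            e_curve = tuning_curve(a, traj, ci, lap_subset=expl_laps[o]) \
                if expl_laps[o] else None
            ne_curve = tuning_curve(a, traj, ci,
                                    lap_subset=nonexpl_laps[o]) \
                if nonexpl_laps[o] else None
            di = difference_index(
                np.nanmean(e_curve.lap_bin_activity, axis=0)
                if e_curve is not None else np.zeros(traj.n_bins),
                np.nanmean(ne_curve.lap_bin_activity, axis=0)
                if ne_curve is not None else np.zeros(traj.n_bins),
                object_bin[o])
            best = {"object_id": o, "percentile": pct, "passed": passed,
                    "di": di, "si_expl": si_e, "si_z_expl": z_e,
                    "recheck_p": np.nan, "retained": False}
        is_oepc = False
        if best["object_id"] >= 0:
            is_oepc, reasons = classify_oepc(best["passed"],
                                             best["si_z_expl"], max_act,
                                             z_threshold, min_activity)
            if is_oepc and recheck:
                p, retained = postexclusion_recheck(a, traj, bouts,
                                                    best["object_id"])
                best["recheck_p"], best["retained"] = p, retained
        else:
            reasons = ["no eligible object (needs >= 3 bouts per label)"]
        rows.append({"cell_id": ci, "max_activity": max_act, "si": si,
                     "si_z": z, "is_place_cell": is_pc,
                     "n_fields": len(fields), "com": com,
                     "is_oepc": bool(is_oepc),
                     "object_id": best["object_id"],
                     "percentile": best["percentile"], "di": best["di"],
                     "si_expl": best["si_expl"],
                     "si_z_expl": best["si_z_expl"],
                     "recheck_p": best["recheck_p"],
                     "retained": best["retained"],
                     "reasons": "; ".join(reasons)})
    return pd.DataFrame(rows)
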