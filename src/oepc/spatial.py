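"""Spatial tuning, spatial information, place-cell classification.

Spatial information (SI) is the Skaggs mutual information between binned
angular position and inferred activity,

    SI = sum_i p_i (r_i / rbar) log2(r_i / rbar)   [bits],

where p_i is the occupancy probability of bin i, r_i the mean inferred
activity in bin i and rbar the overall mean. Significance comes from a
circular-shift shuffle null: the activity trace is rotated by a random
offset (preserving its autocorrelation), SI recomputed 100 times, and the
observed SI converted to a z-score against that null; cells with z >= 1.65
are classified as place cells. Place fields are maximal circularly
contiguous runs of bins exceeding 20% of the cell's maximum, and the field
center of mass (COM) is the angular coordinate of the centroid of the
polygon traced by the tuning curve in polar coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trajectory import PolarTrajectory, bin_centers
from .utils import TWO_PI, circdist, wrap_angle


@dataclass
class SpatialTuningCurve:
    """Laps x bins position-activity summary for one cell.

    ``lap_bin_activity[l, b]`` is the mean activity of the cell over
    frames of lap l in bin b (NaN where the lap never occupied the bin);
    ``occupancy_p`` sums to 1 over occupied bins; ``mean_rate_per_bin``
    pools frames across laps (occupancy-weighted); ``overall_mean`` equals
    sum_i p_i r_i.
    """

    cell_id: int
    lap_ids: np.ndarray
    lap_bin_activity: np.ndarray
    occupancy_p: np.ndarray
    mean_rate_per_bin: np.ndarray
    overall_mean: float


@dataclass
class PlaceField:
    """A circularly contiguous run of bins above 20% of the cell max."""

    bins: np.ndarray     # bin indices in circular order
    peak_bin: int
    com: float           # radians


# ---------------------------------------------------------------------------


def tuning_curve(activity: np.ndarray, traj: PolarTrajectory,
                 cell_id: int = 0, lap_subset=None) -> SpatialTuningCurve:
    """Build the laps x bins tuning curve of one cell.

    Only frames of completed laps enter; reward-consumption frames were
    already unassigned during lap segmentation. ``lap_subset`` restricts
    to a set of lap ids (e.g. exploration laps of one object).
    """
    activity = np.asarray(activity, dtype=float)
    lap_ids = traj.lap_ids if lap_subset is None else np.asarray(sorted(lap_subset))
    n_bins = traj.n_bins
    mat = np.full((len(lap_ids), n_bins), np.nan)
    counts = np.zeros(n_bins)
    sums = np.zeros(n_bins)
    for li, lap in enumerate(lap_ids):
        sel = traj.lap == lap
        b = traj.bin[sel]
        a = activity[sel]
        c = np.bincount(b, minlength=n_bins).astype(float)
        s = np.bincount(b, weights=a, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            mat[li] = np.where(c > 0, s / np.maximum(c, 1), np.nan)
        counts += c
        sums += s
    total = counts.sum()
    occupancy = counts / total if total > 0 else counts
    with np.errstate(invalid="ignore"):
        rate = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    overall = float(np.nansum(occupancy * np.nan_to_num(rate)))
    return SpatialTuningCurve(cell_id=cell_id, lap_ids=lap_ids,
                              lap_bin_activity=mat, occupancy_p=occupancy,
                              mean_rate_per_bin=rate, overall_mean=overall)


def spatial_information(occupancy_p, mean_rate_per_bin) -> float:
    """Skaggs SI in bits; NaN if the overall mean rate is zero.

    Unoccupied bins (p_i = 0 or NaN rate) are excluded; bins with r_i = 0
    contribute zero (the x log x -> 0 limit).
    """
    p = np.asarray(occupancy_p, dtype=float)
    r = np.asarray(mean_rate_per_bin, dtype=float)
    occ = (p > 0) & np.isfinite(r)
    p = p[occ] / p[occ].sum()
    r = r[occ]
    rbar = float(np.sum(p * r))
    if rbar <= 0:
        return np.nan
    ratio = r / rbar
    pos = ratio > 0  # a bin whose ratio underflows contributes its limit, 0
    ratio = ratio[pos]
    return float(np.sum(p[pos] * ratio * np.log2(ratio)))


def si_of_curve(curve: SpatialTuningCurve) -> float:
    return spatial_information(curve.occupancy_p, curve.mean_rate_per_bin)


def _si_from_binned(bins, activity, n_bins):
    """SI from pre-extracted in-lap frames (hot path for the shuffle null)."""
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    sums = np.bincount(bins, weights=activity, minlength=n_bins)
    occ = counts > 0
    p = counts[occ] / counts[occ].sum()
    r = sums[occ] / counts[occ]
    rbar = np.sum(p * r)
    if rbar <= 0:
        return np.nan
    pos = r > 0
    ratio = r[pos] / rbar
    return float(np.sum(p[pos] * ratio * np.log2(ratio)))


def si_zscore(activity: np.ndarray, traj: PolarTrajectory,
              n_shuffles: int = 100, rng=None,
              min_shift_frac: float = 0.05, lap_subset=None):
    """Observed SI and its z-score against a circular-shift null.

    Each shuffle circularly shifts the concatenated in-lap activity trace
    by a random offset uniform over [min_shift, T - min_shift] frames
    (min_shift = ``min_shift_frac`` * T), decoupling activity from
    position while preserving its autocorrelation, and recomputes SI.
    z = (SI_obs - mean_null) / SD_null; NaN if the null SD is zero.

    Returns
    -------
    (si_obs, z, null) : (float, float, ndarray)
    """
    rng = np.random.default_rng(rng)
    activity = np.asarray(activity, dtype=float)
    sel = traj.in_lap if lap_subset is None else np.isin(traj.lap, list(lap_subset))
    bins = traj.bin[sel]
    act = activity[sel]
    n = len(act)
    if n == 0:
        return np.nan, np.nan, np.full(n_shuffles, np.nan)
    si_obs = _si_from_binned(bins, act, traj.n_bins)
    min_shift = max(1, int(round(min_shift_frac * n)))
    if n <= 2 * min_shift:
        raise ValueError("session too short for the circular-shift null")
    offsets = rng.integers(min_shift, n - min_shift, size=n_shuffles,
                           endpoint=True)
    null = np.array([_si_from_binned(bins, np.roll(act, int(o)), traj.n_bins)
                     for o in offsets])
    sd = np.nanstd(null, ddof=1)
    if not np.isfinite(si_obs) or sd == 0 or not np.isfinite(sd):
        return si_obs, np.nan, null
    z = (si_obs - np.nanmean(null)) / sd
    return si_obs, float(z), null


def classify_place_cell(z: float, threshold: float = 1.65) -> bool:
    """Place cell iff the SI z-score is defined and >= threshold."""
    return bool(np.isfinite(z) and z >= threshold)


# ---------------------------------------------------------------------------
# place fields and center of mass


def detect_place_fields(bin_activity, reward_angle: float = 0.0,
                        threshold_frac: float = 0.2) -> list[PlaceField]:
    """Maximal circularly contiguous runs of bins above 20% of the max.

    Fields may wrap across bin n-1 -> 0. An all-zero (or all-NaN) vector
    yields no fields; a uniformly positive vector yields one field
    covering every bin.
    """
    a = np.nan_to_num(np.asarray(bin_activity, dtype=float))
    n = len(a)
    peak = a.max()
    if peak <= 0:
        return []
    above = a > threshold_frac * peak
    if above.all():
        runs = [np.arange(n)]
    else:
        # rotate so the run structure has a False boundary at index 0
        origin = int(np.argmin(above))
        rot = np.roll(above, -origin)
        runs = []
        start = None
        for i, v in enumerate(rot):
            if v and start is None:
                start = i
            elif not v and start is not None:
                runs.append((np.arange(start, i) + origin) % n)
                start = None
        if start is not None:
            runs.append((np.arange(start, n) + origin) % n)
    centers = bin_centers(reward_angle, n)
    fields = []
    for run in runs:
        peak_bin = int(run[np.argmax(a[run])])
        w = a[run]
        com = wrap_angle(np.angle(np.sum(w * np.exp(1j * centers[run]))))
        fields.append(PlaceField(bins=run, peak_bin=peak_bin, com=float(com)))
    return fields


def compute_com(bin_activity, bin_angles=None,
                reward_angle: float = 0.0) -> float:
    """Angular center of mass of the tuning curve, via the polygon centroid.

    The closed polygon has one vertex per bin at polar position
    (radius = bin activity, angle = bin center), ordered by angle; its
    planar (shoelace) area centroid is computed and the centroid's angular
    coordinate returned, in [0, 2*pi). Degenerate polygons (fewer than
    three positive vertices, or near-zero area) fall back to the
    activity-weighted circular mean, with a warning.
    """
    a = np.nan_to_num(np.asarray(bin_activity, dtype=float))
    if bin_angles is None:
        bin_angles = bin_centers(reward_angle, len(a))
    ang = np.asarray(bin_angles, dtype=float)
    if not (a > 0).any():
        raise ValueError("need at least one positive bin")
    order = np.argsort(ang)
    x = a[order] * np.cos(ang[order])
    y = a[order] * np.sin(ang[order])
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    scale = np.max(np.abs(a)) ** 2
    if np.count_nonzero(a > 0) < 3 or abs(area) < 1e-12 * max(scale, 1e-300):
        warnings.warn("degenerate tuning polygon; falling back to "
                      "activity-weighted circular mean")
        return wrap_angle(float(np.angle(np.sum(a * np.exp(1j * ang)))))
    cx = np.sum((x + xn) * cross) / (6.0 * area)
    cy = np.sum((y + yn) * cross) / (6.0 * area)
    return wrap_angle(float(np.arctan2(cy, cx)))


def delta_com(com_a: float, com_b: float) -> float:
    """Absolute circular difference between two COM angles, in [0, pi]."""
    return float(circdist(com_a, com_b))


# ---------------------------------------------------------------------------


def spatial_correlation(vec_a, vec_b, n_shuffles: int = 100, rng=None):
    """Pearson correlation of two bin-activity vectors + rotation null.

    The chance distribution rotates one vector by a random number of bins
    (1 .. n-1) and recomputes r; the reported percentile is the fraction
    of null r values strictly below the observed. Zero-variance input
    gives (nan, nan).
    """
    rng = np.random.default_rng(rng)
    a = np.nan_to_num(np.asarray(vec_a, dtype=float))
    b = np.nan_to_num(np.asarray(vec_b, dtype=float))
    if a.std() == 0 or b.std() == 0:
        return np.nan, np.nan
    r = float(stats.pearsonr(a, b).statistic)
    shifts = rng.integers(1, len(b), size=n_shuffles)
    null = np.array([stats.pearsonr(a, np.roll(b, int(s))).statistic
                     for s in shifts])
    percentile = float(np.mean(null < r))
    return r, percentile
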