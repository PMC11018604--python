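"""Trajectory processing on the annular track.

Raw planar positions are converted to maze-centered polar coordinates,
speed is computed from frame-to-frame displacement, the track is divided
into 24 angular bins anticlockwise from the reward site, anticlockwise laps
are segmented between successive reward-site crossings, behavioral bouts
(the pi/4-before to pi/4-after window around each object) are defined per
lap, and off-track / head-direction-outlier frames within exploration bouts
are flagged against per-bin mean +/- 2 SD bands estimated from pooled
non-exploration frames.

Conventions: frames 0-based, frame ranges half-open, angles in radians
wrapped to [0, 2*pi), anticlockwise positive. Unassigned laps/bins are -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .config import ConfigurationError
from .utils import TWO_PI, circdiff, circdist, circular_mean, circular_sd

EXPLORATION = "exploration"
NON_EXPLORATION = "non-exploration"
EXCLUDED = "excluded"


@dataclass
class PolarTrajectory:
    """Per-frame position of the animal in maze-centered polar coordinates.

    Attributes
    ----------
    t : array of float
        Time of each frame, s.
    x, y : arrays of float
        Raw planar position, cm.
    rho : array of float
        Radial distance from the maze center, cm.
    theta : array of float
        Angular position in [0, 2*pi), anticlockwise.
    speed : array of float
        Planar speed, cm/s.
    hd : array of float or None
        Head direction, radians, if tracked.
    lap : array of int
        Completed-lap index per frame; -1 for frames outside completed
        laps or during reward consumption.
    bin : array of int
        Angular bin in [0, n_bins); -1 where the lap is unassigned.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rho: np.ndarray
    theta: np.ndarray
    speed: np.ndarray
    hd: np.ndarray | None
    lap: np.ndarray
    bin: np.ndarray
    frame_rate: float
    center: tuple
    reward_angle: float
    n_bins: int = 24

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def in_lap(self) -> np.ndarray:
        """Boolean mask of frames belonging to a completed lap."""
        return self.lap >= 0

    @property
    def lap_ids(self) -> np.ndarray:
        laps = np.unique(self.lap)
        return laps[laps >= 0]

    def to_frame(self) -> pd.DataFrame:
        d = {"frame": np.arange(self.n_frames), "t": self.t,
             "x": self.x, "y": self.y, "rho": self.rho, "theta": self.theta,
             "speed": self.speed, "lap": self.lap, "bin": self.bin}
        if self.hd is not None:
            d["hd"] = self.hd
        return pd.DataFrame(d)


@dataclass
class BehavioralBout:
    """One object pass: the window from pi/4 before to pi/4 after an object.

    ``offtrack_mask`` / ``hd_outlier_mask`` / ``indeterminate_mask`` are
    per-frame booleans over [start, end), filled by the flagging functions.
    """

    object_id: int
    lap_id: int
    start: int
    end: int  # half-open
    label: str
    offtrack_mask: np.ndarray | None = None
    hd_outlier_mask: np.ndarray | None = None
    indeterminate_mask: np.ndarray | None = None

    def __len__(self) -> int:
        return self.end - self.start

    def frames(self, traj: PolarTrajectory | None = None) -> np.ndarray:
        """Frame indices of the bout, restricted to its lap if traj given."""
        f = np.arange(self.start, self.end)
        if traj is not None:
            f = f[traj.lap[f] == self.lap_id]
        return f

    def valid_frames(self, traj: PolarTrajectory,
                     exclude_offtrack: bool = False,
                     exclude_hd_outliers: bool = False) -> np.ndarray:
        """Frame indices after applying the requested exclusion masks."""
        f = np.arange(self.start, self.end)
        keep = traj.lap[f] == self.lap_id
        if exclude_offtrack and self.offtrack_mask is not None:
            keep &= ~self.offtrack_mask
            if self.indeterminate_mask is not None:
                keep &= ~self.indeterminate_mask
        if exclude_hd_outliers and self.hd_outlier_mask is not None:
            keep &= ~self.hd_outlier_mask
        return f[keep]


# ---------------------------------------------------------------------------
# elementary conversions


def to_polar(xy: np.ndarray, center) -> tuple[np.ndarray, np.ndarray]:
    """Convert planar positions to (rho, theta) about the maze center.

    rho is the Euclidean distance to ``center``; theta is measured
    anticlockwise from the +x axis and wrapped to [0, 2*pi). A frame
    exactly at the center has undefined angle: the previous frame's theta
    is propagated (0 for a leading run) with a warning.
    """
    xy = np.asarray(xy, dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("positions must be finite")
    dx = xy[:, 0] - center[0]
    dy = xy[:, 1] - center[1]
    rho = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), TWO_PI)
    at_center = rho == 0
    if at_center.any():
        warnings.warn("frame(s) exactly at maze center: propagating the "
                      "previous frame's angle")
        idx = np.where(~at_center, np.arange(len(rho)), -1)
        np.maximum.accumulate(idx, out=idx)
        theta = np.where(idx >= 0, theta[np.maximum(idx, 0)], 0.0)
    return rho, theta


def compute_speed(xy: np.ndarray, frame_rate: float,
                  smooth_window: int = 5) -> np.ndarray:
    """Frame-wise planar speed (cm/s), boxcar-smoothed.

    Speed at frame i is the displacement from frame i-1 times the frame
    rate; frame 0 repeats frame 1's value. ``smooth_window`` <= 1 disables
    smoothing.
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        raise ValueError("need at least 2 frames to compute speed")
    step = np.hypot(*np.diff(xy, axis=0).T) * frame_rate
    speed = np.concatenate([[step[0]], step])
    if smooth_window and smooth_window > 1:
        speed = uniform_filter1d(speed, size=smooth_window, mode="nearest")
    return speed


def assign_bins(theta, reward_angle: float, n_bins: int = 24) -> np.ndarray:
    """Assign angular bins, bin 0 starting at the reward site.

    Bins advance anticlockwise, each spanning 2*pi/n_bins, half-open
    [lower, upper): an angle exactly on a boundary belongs to the bin it
    lower-bounds.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    rel = np.mod(np.asarray(theta, dtype=float) - reward_angle, TWO_PI)
    b = np.floor(rel / (TWO_PI / n_bins)).astype(int)
    return np.where(b >= n_bins, 0, b)


def bin_centers(reward_angle: float, n_bins: int = 24) -> np.ndarray:
    """Angular centers of the bins, wrapped to [0, 2*pi)."""
    width = TWO_PI / n_bins
    return np.mod(reward_angle + width * (np.arange(n_bins) + 0.5), TWO_PI)


# ---------------------------------------------------------------------------
# lap segmentation


def unwrap_progress(theta, reward_angle: float) -> np.ndarray:
    """Cumulative anticlockwise angular progress relative to the reward site.

    Starts in [0, 2*pi); each completed anticlockwise lap adds 2*pi.
    """
    rel = np.mod(np.asarray(theta, dtype=float) - reward_angle, TWO_PI)
    return np.unwrap(rel)


def segment_laps(theta, reward_angle: float,
                 tolerance: float = np.pi / 12,
                 excluded_ranges=()) -> np.ndarray:
    """Assign a completed-lap index to every frame (-1 = unassigned).

    A lap is a maximal frame span between successive anticlockwise
    reward-site crossings with net progress 2*pi. Laps whose trajectory
    regresses clockwise by more than ``tolerance`` below the running
    maximum are discarded. ``excluded_ranges`` are half-open (start, end)
    frame ranges (reward consumption) forced to -1.
    """
    phi = unwrap_progress(theta, reward_angle)
    n = len(phi)
    lap = np.full(n, -1, dtype=int)
    # a lap boundary is the first frame at or above each 2*pi level
    level = np.floor(phi / TWO_PI).astype(int)
    m0 = level[0]
    boundaries = {}
    for m in range(m0, level.max() + 1):
        hit = level >= m
        boundaries[m] = int(np.argmax(hit)) if hit.any() else None
    lap_count = 0
    for m in range(m0, level.max()):
        s, e = boundaries[m], boundaries[m + 1]
        if s is None or e is None or e <= s:
            continue
        seg = phi[s:e]
        regression = np.max(np.maximum.accumulate(seg) - seg)
        if regression > tolerance:
            lap_count += 1  # the pass happened but is discarded
            continue
        lap[s:e] = lap_count
        lap_count += 1
    for (s, e) in excluded_ranges:
        lap[int(s):int(e)] = -1
    if not (lap >= 0).any():
        warnings.warn("no completed laps found")
    return lap


# ---------------------------------------------------------------------------
# bouts


def define_bouts(traj: PolarTrajectory, object_angles,
                 labels=None, window: float = np.pi / 4) -> list[BehavioralBout]:
    """One behavioral bout per (object, completed lap).

    The bout spans the angular window [object - window, object + window)
    within the lap. ``labels`` maps (object_id, lap_id) to
    "exploration" / "non-exploration" / "excluded"; missing passes are
    labeled excluded. Objects closer than 2*window raise, since their
    windows would overlap.
    """
    object_angles = [float(a) for a in object_angles]
    for i in range(len(object_angles)):
        for j in range(i + 1, len(object_angles)):
            if circdist(object_angles[i], object_angles[j]) < 2 * window:
                raise ConfigurationError(
                    "object windows overlap: objects must be at least "
                    f"{2 * window:.3f} rad apart")
    labels = labels or {}
    bouts = []
    for lap_id in traj.lap_ids:
        lap_frames = np.where(traj.lap == lap_id)[0]
        for obj_id, obj_angle in enumerate(object_angles):
            d = circdiff(traj.theta[lap_frames], obj_angle)
            inside = (d >= -window) & (d < window)
            if not inside.any():
                continue
            sel = lap_frames[inside]
            start, end = int(sel[0]), int(sel[-1]) + 1
            label = labels.get((obj_id, int(lap_id)), EXCLUDED)
            bouts.append(BehavioralBout(object_id=obj_id, lap_id=int(lap_id),
                                        start=start, end=end, label=label))
    return bouts


# ---------------------------------------------------------------------------
# exclusion masks

def _per_bin_stats(values, bins, n_bins):
    """Per-bin mean and sample SD; NaN where fewer than 2 samples."""
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    for b in range(n_bins):
        v = values[bins == b]
        if len(v) >= 2:
            mean[b] = v.mean()
            sd[b] = v.std(ddof=1)
    return mean, sd


def flag_offtrack(bouts, traj: PolarTrajectory, n_sd: float = 2.0) -> None:
    """Flag off-track exploration frames, in place.

    Per angular bin, the mean and SD of rho are computed from frames of
    pooled non-exploration bouts only; exploration frames whose rho falls
    outside mean +/- ``n_sd`` * SD of their bin are flagged off-track.
    Exploration frames in bins with fewer than two non-exploration frames
    are flagged indeterminate. Non-exploration bouts get all-False masks.
    """
    ref = np.concatenate([b.frames(traj) for b in bouts
                          if b.label == NON_EXPLORATION] or [np.array([], int)])
    mean, sd = _per_bin_stats(traj.rho[ref], traj.bin[ref], traj.n_bins)
    expl = np.concatenate([b.frames(traj) for b in bouts
                           if b.label == EXPLORATION] or [np.array([], int)])
    bad = np.isnan(mean) & np.isin(np.arange(traj.n_bins), traj.bin[expl])
    if bad.any():
        warnings.warn(f"bins {np.where(bad)[0].tolist()} have <2 "
                      "non-exploration frames; exploration frames there "
                      "are indeterminate")
    lo, hi = mean - n_sd * sd, mean + n_sd * sd
    for b in bouts:
        m = np.zeros(len(b), dtype=bool)
        ind = np.zeros(len(b), dtype=bool)
        if b.label == EXPLORATION:
            f = np.arange(b.start, b.end)
            ok = traj.lap[f] == b.lap_id
            fb = traj.bin[f]
            with np.errstate(invalid="ignore"):
                out = (traj.rho[f] < lo[fb]) | (traj.rho[f] > hi[fb])
            m[:] = out & ok
            ind[:] = np.isnan(mean[fb]) & ok
        b.offtrack_mask = m
        b.indeterminate_mask = ind


def flag_hd_outliers(bouts, traj: PolarTrajectory, n_sd: float = 2.0) -> None:
    """Flag head-direction-outlier exploration frames, in place.

    Same per-bin +/- ``n_sd`` SD rule as :func:`flag_offtrack`, applied to
    head direction using circular statistics (circular mean; circular SD
    sqrt(-2 ln R)), so the rule is invariant to the 0/2*pi wrap.
    """
    if traj.hd is None:
        warnings.warn("no head direction available; hd outlier masks empty")
        for b in bouts:
            b.hd_outlier_mask = np.zeros(len(b), dtype=bool)
        return
    ref = np.concatenate([b.frames(traj) for b in bouts
                          if b.label == NON_EXPLORATION] or [np.array([], int)])
    mean = np.full(traj.n_bins, np.nan)
    sd = np.full(traj.n_bins, np.nan)
    for i in range(traj.n_bins):
        v = traj.hd[ref][traj.bin[ref] == i]
        if len(v) >= 2:
            mean[i] = circular_mean(v)
            sd[i] = circular_sd(v)
    for b in bouts:
        m = np.zeros(len(b), dtype=bool)
        if b.label == EXPLORATION:
            f = np.arange(b.start, b.end)
            ok = traj.lap[f] == b.lap_id
            fb = traj.bin[f]
            with np.errstate(invalid="ignore"):
                dev = circdist(traj.hd[f], mean[fb])
                out = dev > n_sd * sd[fb]
            m[:] = np.where(np.isnan(mean[fb]), False, out) & ok
        b.hd_outlier_mask = m


# ---------------------------------------------------------------------------
# assembly


def process_trajectory(t, xy, hd, config, labels=None,
                       excluded_ranges=(), smooth_window: int = 5,
                       lap_tolerance: float = np.pi / 12):
    """Full preprocessing: polar conversion, speed, bins, laps, bouts.

    Parameters
    ----------
    t, xy, hd : arrays
        Frame times (s), planar positions (n x 2, cm), head direction
        (radians, or None).
    config : SessionConfig
        Maze geometry and reward/object angles.
    labels : mapping
        (object_id, lap_id) -> bout label, e.g. from annotation or the
        simulator's ground truth.
    excluded_ranges : iterable of (start, end)
        Reward-consumption frame ranges to unassign.

    Returns
    -------
    (PolarTrajectory, list of BehavioralBout)
    """
    xy = np.asarray(xy, dtype=float)
    rho, theta = to_polar(xy, config.center)
    speed = compute_speed(xy, config.frame_rate, smooth_window)
    lap = segment_laps(theta, config.reward_angle, lap_tolerance,
                       excluded_ranges)
    bins = assign_bins(theta, config.reward_angle, config.n_bins)
    bins = np.where(lap >= 0, bins, -1)
    traj = PolarTrajectory(t=np.asarray(t, float), x=xy[:, 0], y=xy[:, 1],
                           rho=rho, theta=theta, speed=speed,
                           hd=None if hd is None else np.asarray(hd, float),
                           lap=lap, bin=bins, frame_rate=config.frame_rate,
                           center=config.center,
                           reward_angle=config.reward_angle,
                           n_bins=config.n_bins)
    bouts = define_bouts(traj, config.object_angles, labels)
    return traj, bouts
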