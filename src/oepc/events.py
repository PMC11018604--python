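"""Reward-associated cells, speed-drop periods, speed-activity coupling.

Speed-drop periods are contiguous sub-threshold-speed runs within laps
(dual thresholds with hysteresis to avoid chatter) classified by location
into exploration (inside an exploration bout / exploration-associated
field), reward (near the reward site) or other; the remaining in-lap
frames form the baseline set. A cell is reward-associated (RA) if its
tuning peak over the reward-proximal bins exceeds the mean + 2 SD of its
24-bin activity vector. Negative speed-activity coupling is tested per
period against a within-window circular-shift null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trajectory import EXPLORATION, PolarTrajectory
from .utils import circdist


@dataclass
class SpeedDropEvent:
    kind: str              # "exploration" | "reward" | "other"
    start: int
    end: int               # half-open
    lap_id: int
    min_speed: float
    object_id: int = -1

    def frames(self) -> np.ndarray:
        return np.arange(self.start, self.end)


@dataclass
class CorrelationResult:
    cell_id: int
    kind: str
    r: float
    percentile: float      # fraction of null r values below the observed
    significant: bool      # significant *negative* coupling


def reward_proximal_bins(reward_bin: int, n_bins: int = 24,
                         window: int = 3) -> list:
    """The ``window`` bins centered on the reward bin, circularly."""
    half = window // 2
    return [(reward_bin + k) % n_bins for k in range(-half, half + 1)]


def identify_ra_cells(mean_rate_per_bin, reward_bin: int = 0,
                      window: int = 3, n_sd: float = 2.0) -> bool:
    """Reward-associated iff the peak over reward-proximal bins exceeds
    mean + ``n_sd`` * SD (sample SD) of the whole bin vector.

    A zero-variance vector is never RA, and a peak far from the reward
    bins never qualifies regardless of height.
    """
    vec = np.nan_to_num(np.asarray(mean_rate_per_bin, dtype=float))
    sd = vec.std(ddof=1)
    if sd == 0:
        return False
    sel = reward_proximal_bins(reward_bin, len(vec), window)
    return bool(vec[sel].max() > vec.mean() + n_sd * sd)


# ---------------------------------------------------------------------------


def annotate_speed_drops(traj: PolarTrajectory, bouts, reward_angle: float,
                         field_bins_by_object: dict | None = None,
                         enter: float = 2.0, exit: float = 4.0,
                         reward_window: float = np.pi / 8,
                         min_frames: int = 3):
    """Detect and classify sub-threshold-speed periods within laps.

    A run starts when smoothed speed falls below ``enter`` cm/s and ends
    when it rises above ``exit`` cm/s (or the lap ends). Runs overlapping
    an exploration bout near its object (or the object's
    exploration-associated field bins, if given) are "exploration"; runs
    whose median angle lies within ``reward_window`` of the reward site
    are "reward"; the rest are "other". Reward-consumption frames are
    outside laps and never enter any run.

    Returns (events, baseline_mask): the baseline is every in-lap frame
    belonging to no event, so events + baseline partition the in-lap set.
    """
    events = []
    n = traj.n_frames
    in_lap = traj.lap >= 0
    expl_frames_by_obj = {}
    for b in bouts:
        if b.label == EXPLORATION:
            expl_frames_by_obj.setdefault(b.object_id, []).append(
                b.frames(traj))
    expl_mask = {o: np.zeros(n, dtype=bool) for o in expl_frames_by_obj}
    for o, fr in expl_frames_by_obj.items():
        expl_mask[o][np.concatenate(fr)] = True

    i = 0
    while i < n:
        if in_lap[i] and traj.speed[i] < enter:
            j = i
            lap = traj.lap[i]
            while j < n and in_lap[j] and traj.lap[j] == lap \
                    and traj.speed[j] <= exit:
                j += 1
            if j - i >= min_frames:
                run = np.arange(i, j)
                kind, oid = "other", -1
                for o, mask in expl_mask.items():
                    if mask[run].any():
                        kind, oid = "exploration", o
                        break
                if kind == "other" and field_bins_by_object:
                    for o, fb in field_bins_by_object.items():
                        if np.isin(traj.bin[run], list(fb)).any() \
                                and o in expl_mask and expl_mask[o][run].any():
                            kind, oid = "exploration", o
                            break
                if kind == "other":
                    med_theta = float(np.median(traj.theta[run]))
                    if circdist(med_theta, reward_angle) <= reward_window:
                        kind = "reward"
                events.append(SpeedDropEvent(kind=kind, start=i, end=j,
                                             lap_id=int(lap),
                                             min_speed=float(
                                                 traj.speed[run].min()),
                                             object_id=oid))
            i = j
        else:
            i += 1
    baseline = in_lap.copy()
    for ev in events:
        baseline[ev.start:ev.end] = False
    return events, baseline


def period_mean_activity(activity, events, baseline_mask) -> dict:
    """Mean inferred activity per period kind, plus baseline.

    Kinds with no frames give NaN.
    """
    activity = np.asarray(activity, dtype=float)
    out = {}
    for kind in ("exploration", "reward", "other"):
        f = [ev.frames() for ev in events if ev.kind == kind]
        out[kind] = float(activity[np.concatenate(f)].mean()) if f else np.nan
    out["baseline"] = float(activity[baseline_mask].mean()) \
        if baseline_mask.any() else np.nan
    return out


def speed_activity_correlation(activity, speed, frame_range,
                               n_shuffles: int = 100, rng=None,
                               min_frames: int = 10, cell_id: int = 0,
                               kind: str = "other") -> CorrelationResult:
    """Pearson speed-activity correlation in a window, with shift null.

    The null circularly shifts the activity within the window (offsets
    1..L-1), preserving both series' autocorrelation. Negative coupling is
    significant iff the observed r lies below the 5th percentile of the
    null, i.e. fewer than 5% of null r values fall below it.
    """
    rng = np.random.default_rng(rng)
    s, e = frame_range
    a = np.asarray(activity, dtype=float)[s:e]
    v = np.asarray(speed, dtype=float)[s:e]
    if len(a) < min_frames:
        raise ValueError(f"window shorter than {min_frames} frames")
    if a.std() == 0 or v.std() == 0:
        return CorrelationResult(cell_id, kind, np.nan, np.nan, False)
    r = float(stats.pearsonr(v, a).statistic)
    offsets = rng.integers(1, len(a), size=n_shuffles)
    null = np.array([stats.pearsonr(v, np.roll(a, int(o))).statistic
                     for o in offsets])
    percentile = float(np.mean(null < r))
    return CorrelationResult(cell_id, kind, r, percentile,
                             bool(percentile < 0.05))
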