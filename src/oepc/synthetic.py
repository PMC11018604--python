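"""Synthetic annular-maze sessions with known ground truth.

The generator emulates the statistical structure the analysis assumes:
anticlockwise laps on an annular track, spontaneous exploration bouts at
fixed object positions (lower speed, longer dwell near the object, and in
a configurable fraction of bouts an off-track radial excursion toward the
object), a reward pause each lap with the consumption period excluded, and
a neural population of classical place cells (cPCs), exploration-gated
place cells (oePCs) whose field sits a fixed lead distance before their
object and who are silent on non-exploration passes, reward-associated
(RA) cells, and untuned cells. Activity is sparse positive events with
lognormal amplitudes, resembling deconvolved/inferred traces in arbitrary
units. All randomness flows from the seeds in the two config objects, so
identical configs give bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .config import AlignmentError, PopulationConfig, SessionConfig
from .trajectory import (EXPLORATION, NON_EXPLORATION, PolarTrajectory,
                         BehavioralBout, process_trajectory)
from .utils import TWO_PI, circdist, wrap_angle

ROLE_CPC = "cPC"
ROLE_OEPC = "oePC"
ROLE_RA = "RA"
ROLE_UNTUNED = "untuned"

_PHI_JITTER_RUN = 0.004   # rad/frame while running
_PHI_JITTER_PAUSE = 0.001  # rad/frame while paused
_PORT_OFFSET = 0.02       # rad before the reward port where the animal stops


@dataclass
class GroundTruth:
    """Per-cell roles and per-pass bout labels of a synthetic session."""

    cells: pd.DataFrame        # cell_id, role, preferred_angle, object_id
    labels: dict               # (object_id, lap_id) -> bout label
    offtrack_bouts: set        # (object_id, lap_id) with an injected excursion
    excluded_ranges: list      # reward-consumption (start, end) frame ranges
    seed: int


def _dip_factor(dist, half_width, floor):
    """Multiplicative speed factor ramping from 1 at half_width to floor at 0."""
    if dist >= half_width:
        return 1.0
    return floor + (1.0 - floor) * (dist / half_width)


def generate_trajectory(config: SessionConfig):
    """Simulate the behavioral session.

    Returns
    -------
    (traj, bouts, truth) : (PolarTrajectory, list of BehavioralBout, GroundTruth)
        The trajectory is fully processed (polar, speed, bins, laps) and
        the bouts carry the generated exploration labels.
    """
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.frame_rate
    mid = config.mid_radius
    n_obj = len(config.object_angles)
    obj_rel = [wrap_angle(a - config.reward_angle) for a in config.object_angles]

    # plan every pass up front so label draws are independent of kinematics
    labels, offtrack, dwell_len = {}, set(), {}
    other_pause = {}
    for lap in range(config.n_laps):
        for oid in range(n_obj):
            explore = rng.random() < config.p_explore
            labels[(oid, lap)] = EXPLORATION if explore else NON_EXPLORATION
            if explore:
                if rng.random() < config.p_offtrack:
                    offtrack.add((oid, lap))
                d = max(0.3, rng.normal(config.explore_dwell_s,
                                        0.15 * config.explore_dwell_s))
                dwell_len[(oid, lap)] = max(1, int(round(d * config.frame_rate)))
        if rng.random() < config.p_other_pause:
            for _ in range(50):
                cand = rng.uniform(0.3, TWO_PI - 0.5)
                ang = wrap_angle(config.reward_angle + cand)
                clear = all(circdist(ang, a) > np.pi / 4 + 0.1
                            for a in config.object_angles)
                if clear and circdist(ang, config.reward_angle) > np.pi / 6:
                    other_pause[lap] = cand
                    break

    phi_global = []          # cumulative anticlockwise progress, rad
    excursion = []           # radial bump per frame, cm
    hd_override = []         # NaN, or an absolute head direction to inject
    excluded_ranges = []

    def emit(progress, bump=0.0, hd_to=np.nan):
        phi_global.append(progress)
        excursion.append(bump)
        hd_override.append(hd_to)

    for lap in range(config.n_laps):
        phi = 0.01 if lap == 0 else phi_global[-1] - TWO_PI * lap
        pending = sorted([(obj_rel[oid], "object", oid)
                          for oid in range(n_obj)
                          if labels[(oid, lap)] == EXPLORATION]
                         + ([(other_pause[lap], "other", -1)]
                            if lap in other_pause else []))
        pending = [p for p in pending if p[0] > phi]
        end_phi = TWO_PI - _PORT_OFFSET
        while phi < end_phi:
            m = 1.0
            theta_here = wrap_angle(config.reward_angle + phi)
            for oid in range(n_obj):
                if labels[(oid, lap)] == EXPLORATION:
                    m *= _dip_factor(circdist(theta_here, config.object_angles[oid]),
                                     config.dip_half_width,
                                     config.speed_dip_factor)
            m *= _dip_factor(end_phi - phi, config.dip_half_width,
                             config.speed_dip_factor)
            omega = config.run_speed * m / mid
            phi += omega * dt + rng.normal(0.0, _PHI_JITTER_RUN)
            emit(TWO_PI * lap + phi)
            while pending and phi >= pending[0][0]:
                _, kind, oid = pending.pop(0)
                if kind == "object":
                    n_d = dwell_len[(oid, lap)]
                    bump_on = (oid, lap) in offtrack
                    amp = config.offtrack_amplitude_sd * config.radial_noise_sd
                    window = np.sin(np.linspace(0, np.pi, n_d)) ** 2
                    out_dir = wrap_angle(config.object_angles[oid])
                    for k in range(n_d):
                        phi += rng.normal(0.0, _PHI_JITTER_PAUSE)
                        emit(TWO_PI * lap + phi,
                             bump=amp * window[k] if bump_on else 0.0,
                             hd_to=out_dir if bump_on else np.nan)
                else:
                    n_d = max(1, int(round(config.other_pause_s
                                           * config.frame_rate)))
                    for _ in range(n_d):
                        phi += rng.normal(0.0, _PHI_JITTER_PAUSE)
                        emit(TWO_PI * lap + phi)
        # hesitation at the port (in-lap), then consumption (excluded)
        for _ in range(int(round(config.pre_reward_pause_s * config.frame_rate))):
            phi += rng.normal(0.0, _PHI_JITTER_PAUSE)
            emit(TWO_PI * lap + phi)
        start_excl = len(phi_global)
        phi = TWO_PI + 0.01
        for _ in range(max(1, int(round(config.reward_pause_s
                                        * config.frame_rate)))):
            phi += rng.normal(0.0, _PHI_JITTER_PAUSE)
            emit(TWO_PI * lap + phi)
        excluded_ranges.append((start_excl, len(phi_global)))

    phi_global = np.asarray(phi_global)
    n = len(phi_global)
    theta = wrap_angle(config.reward_angle + phi_global)

    noise = gaussian_filter1d(rng.normal(0.0, 1.0, n), sigma=4.0)
    noise *= config.radial_noise_sd / noise.std()
    rho = mid + noise + np.asarray(excursion)

    cx, cy = config.center
    x = cx + rho * np.cos(theta)
    y = cy + rho * np.sin(theta)
    t = np.arange(n) * dt

    # head direction: heading of the velocity vector + noise; during
    # off-track excursions the animal faces the (outward) object instead
    dx = np.diff(x, prepend=x[0])
    dy = np.diff(y, prepend=y[0])
    step = np.hypot(dx, dy)
    heading = np.arctan2(dy, dx)
    for i in range(1, n):
        if step[i] < 0.15:
            heading[i] = heading[i - 1]
    hd = wrap_angle(heading + rng.normal(0.0, config.hd_noise_sd, n))
    override = np.asarray(hd_override)
    inject = np.isfinite(override)
    hd[inject] = wrap_angle(override[inject]
                            + rng.normal(0.0, config.hd_noise_sd,
                                         int(inject.sum())))

    traj, bouts = process_trajectory(
        t, np.column_stack([x, y]), hd, config, labels=labels,
        excluded_ranges=excluded_ranges)
    truth = GroundTruth(cells=pd.DataFrame(), labels=labels,
                        offtrack_bouts=offtrack,
                        excluded_ranges=excluded_ranges, seed=config.seed)
    return traj, bouts, truth


# ---------------------------------------------------------------------------


def generate_activity(traj: PolarTrajectory, bouts, pop: PopulationConfig,
                      truth: GroundTruth | None = None):
    """Simulate the cells x frames activity matrix.

    cPCs fire in every lap with Gaussian angular tuning; oePCs carry the
    same tuning, centered ``oepc_lead_distance`` (track cm) before their
    object, but only inside exploration bouts of that object; RA cells are
    tuned to the reward site; untuned cells emit background only. Events
    are Poisson-thinned per frame with lognormal amplitudes so that the
    expected trace value at the tuning peak equals ``peak_rate`` and the
    background expectation equals ``noise_rate``.

    Returns
    -------
    (activity, truth) : (ndarray of shape (n_cells, n_frames), GroundTruth)
    """
    rng = np.random.default_rng(pop.seed)
    n_frames = traj.n_frames
    if bouts and max(b.end for b in bouts) > n_frames:
        raise AlignmentError("bout frame ranges exceed the trajectory length")

    in_lap = traj.lap >= 0
    mid = float(np.median(traj.rho[in_lap])) if in_lap.any() \
        else float(np.median(traj.rho))
    lead_angle = pop.oepc_lead_distance / mid

    object_ids = sorted({b.object_id for b in bouts})
    object_angle = {}
    # recover each object's angle from the bout window midpoint
    for oid in object_ids:
        bs = [b for b in bouts if b.object_id == oid]
        mids = [circular_midpoint(traj.theta[b.start],
                                  traj.theta[b.end - 1]) for b in bs]
        object_angle[oid] = float(np.angle(np.sum(np.exp(1j * np.array(mids)))))
        object_angle[oid] = wrap_angle(object_angle[oid])

    expl_gate = {oid: np.zeros(n_frames, dtype=bool) for oid in object_ids}
    for b in bouts:
        if b.label == EXPLORATION:
            expl_gate[b.object_id][b.frames(traj)] = True

    amp_mean = pop.event_amplitude_mean
    sigma2 = np.log(1.0 + pop.event_amplitude_cv ** 2)
    mu = np.log(amp_mean) - sigma2 / 2.0 if amp_mean > 0 else 0.0

    rows, records = [], []
    cell_id = 0

    def emit_cell(rate, role, pref, oid):
        nonlocal cell_id
        lam = np.clip(rate, 0.0, None) / max(amp_mean, 1e-12)
        counts = rng.poisson(lam)
        total = int(counts.sum())
        a = np.zeros(n_frames)
        if total:
            amps = rng.lognormal(mu, np.sqrt(sigma2), total)
            idx = np.repeat(np.arange(n_frames), counts)
            a = np.bincount(idx, weights=amps, minlength=n_frames)
        rows.append(a)
        records.append({"cell_id": cell_id, "role": role,
                        "preferred_angle": pref,
                        "object_id": oid})
        cell_id += 1

    gain = pop.peak_rate - pop.noise_rate
    for _ in range(pop.n_cpc):
        pref = rng.uniform(0.0, TWO_PI)
        tuning = np.exp(-circdist(traj.theta, pref) ** 2
                        / (2 * pop.tuning_width ** 2))
        emit_cell(pop.noise_rate + gain * tuning, ROLE_CPC, pref, -1)
    for i in range(pop.n_oepc):
        if not object_ids:
            raise AlignmentError("oePCs requested but the session has no bouts")
        oid = object_ids[i % len(object_ids)]
        pref = wrap_angle(object_angle[oid] - lead_angle)
        tuning = np.exp(-circdist(traj.theta, pref) ** 2
                        / (2 * pop.tuning_width ** 2))
        emit_cell(pop.noise_rate + gain * tuning * expl_gate[oid],
                  ROLE_OEPC, pref, oid)
    for _ in range(pop.n_ra):
        pref = traj.reward_angle
        tuning = np.exp(-circdist(traj.theta, pref) ** 2
                        / (2 * pop.tuning_width ** 2))
        emit_cell(pop.noise_rate + gain * tuning, ROLE_RA, pref, -1)
    for _ in range(pop.n_untuned):
        emit_cell(np.full(n_frames, pop.noise_rate), ROLE_UNTUNED, np.nan, -1)

    activity = np.array(rows) if rows else np.zeros((0, n_frames))
    cells = pd.DataFrame(records,
                         columns=["cell_id", "role", "preferred_angle",
                                  "object_id"])
    if truth is None:
        truth = GroundTruth(cells=cells, labels={}, offtrack_bouts=set(),
                            excluded_ranges=[], seed=pop.seed)
    else:
        truth.cells = cells
    return activity, truth


def circular_midpoint(a: float, b: float) -> float:
    """Midpoint of the shorter arc from a to b."""
    return wrap_angle(a + 0.5 * np.mod(b - a, TWO_PI)) \
        if np.mod(b - a, TWO_PI) <= np.pi \
        else wrap_angle(b + 0.5 * np.mod(a - b, TWO_PI))


def generate_session(session_config: SessionConfig,
                     population_config: PopulationConfig):
    """Convenience wrapper: trajectory + bouts + activity + ground truth."""
    traj, bouts, truth = generate_trajectory(session_config)
    activity, truth = generate_activity(traj, bouts, population_config, truth)
    return traj, bouts, activity, truth
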