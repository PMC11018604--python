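import numpy as np
import pytest

import oepc


@pytest.fixture(scope="session")
def default_session():
    """The default synthetic session: 20 laps, 3 objects, 30 cPC / 10 oePC /
    10 RA / 50 untuned cells, master seed 0."""
    cfg = oepc.PipelineConfig(seed=0)
    traj, bouts, activity, truth = oepc.generate_session(cfg.session,
                                                         cfg.population)
    oepc.flag_offtrack(bouts, traj)
    oepc.flag_hd_outliers(bouts, traj)
    return cfg, traj, bouts, activity, truth


@pytest.fixture(scope="session")
def default_classification(default_session):
    cfg, traj, bouts, activity, truth = default_session
    rng = np.random.default_rng(cfg.analysis.seed)
    cls = oepc.classify_session(activity, traj, bouts, rng=rng)
    return cls.merge(truth.cells[["cell_id", "role"]], on="cell_id")


def make_circular_trajectory(n_laps=3, frames_per_lap=240, radius=12.5,
                             reward_angle=0.0, n_bins=24, frame_rate=30.0,
                             rho=None, hd=None):
    """Uniform anticlockwise circular motion as a PolarTrajectory."""
    n = n_laps * frames_per_lap + 1
    phi = np.linspace(0.0, 2 * np.pi * n_laps, n) + 1e-6
    theta = np.mod(reward_angle + phi, 2 * np.pi)
    rho = np.full(n, float(radius)) if rho is None else np.asarray(rho, float)
    x = 15.0 + rho * np.cos(theta)
    y = 15.0 + rho * np.sin(theta)
    lap = oepc.segment_laps(theta, reward_angle)
    bins = np.where(lap >= 0,
                    oepc.assign_bins(theta, reward_angle, n_bins), -1)
    speed = oepc.compute_speed(np.column_stack([x, y]), frame_rate)
    return oepc.PolarTrajectory(
        t=np.arange(n) / frame_rate, x=x, y=y, rho=rho, theta=theta,
        speed=speed, hd=hd, lap=lap, bin=bins, frame_rate=frame_rate,
        center=(15.0, 15.0), reward_angle=reward_angle, n_bins=n_bins)
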