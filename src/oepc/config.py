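"""Session, population and analysis configuration.

The defaults mirror the study conditions: a square (30 cm side) or circular
(35 cm diameter) maze with a concentric 20 cm cylinder forming an annular
track about 5 cm wide, an overhead camera at 30 frames/s, the track divided
into 24 angular bins anticlockwise from the reward site, and the statistical
thresholds used throughout (z >= 1.65 for spatial information, the 99%
bout-shuffle criterion, the 2 arb. unit activity floor, the 20% place-field
rule, mean +/- 2 SD exclusion bands, 95th-percentile decoding significance).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from .utils import TWO_PI, circdist

CONFIG_SCHEMA_VERSION = 1


class GeometryError(ValueError):
    """Maze dimensions are mutually inconsistent."""


class AlignmentError(ValueError):
    """Trajectory and activity matrices disagree on frame count."""


class ConfigurationError(ValueError):
    """Invalid analysis configuration (e.g. overlapping object windows)."""


@dataclass
class SessionConfig:
    """Geometry and behavioral parameters of one annular-maze session.

    Parameters
    ----------
    maze_shape : {"square", "circular"}
        Outer wall shape. ``outer_size`` is the side length of the square
        or the diameter of the circle, in cm.
    inner_diameter : float
        Diameter of the central cylinder (cm); the annular track runs
        between the cylinder and the outer wall.
    track_width : float
        Nominal radial width of the track (cm).
    reward_angle : float
        Angular position of the reward port, radians. Laps and angular
        bin 0 both start here.
    object_angles : tuple of float
        Angular positions of the objects (radians). Must be distinct from
        each other and the reward by at least pi/2 so behavioral-bout
        windows (pi/4 either side of an object) never overlap.
    n_laps : int
        Number of anticlockwise laps to simulate.
    frame_rate : float
        Behavioral camera frame rate, Hz.
    p_explore : float
        Probability that an object pass is an exploration bout.
    seed : int
        Seed for the trajectory generator.

    The remaining fields shape the simulated behavior: the running speed
    along the track, the multiplicative speed dip on exploration approaches,
    the dwell pause at an explored object, the probability and amplitude of
    off-track radial excursions, radial/heading noise, and the pauses at the
    reward port (the consumption pause is excluded from analysis).
    """

    maze_shape: str = "square"
    outer_size: float = 30.0
    inner_diameter: float = 20.0
    track_width: float = 5.0
    reward_angle: float = 0.0
    object_angles: tuple = (np.pi / 2, np.pi, 3 * np.pi / 2)
    n_laps: int = 20
    frame_rate: float = 30.0
    p_explore: float = 0.4
    seed: int = 0
    # behavior-shape parameters (see docs/methods.md)
    run_speed: float = 12.0          # cm/s along the track
    speed_dip_factor: float = 0.25   # multiplicative dip at an explored object
    dip_half_width: float = np.pi / 8
    explore_dwell_s: float = 1.0     # pause at the object during exploration
    p_offtrack: float = 0.5          # fraction of exploration bouts with excursion
    offtrack_amplitude_sd: float = 3.0  # excursion height in radial-noise SDs
    radial_noise_sd: float = 0.4     # cm
    pre_reward_pause_s: float = 0.5  # hesitation at the port, kept in-lap
    reward_pause_s: float = 1.5      # consumption, excluded from analysis
    p_other_pause: float = 0.15      # chance per lap of a pause away from objects
    other_pause_s: float = 0.7
    hd_noise_sd: float = 0.15        # radians
    n_bins: int = 24

    def __post_init__(self):
        self.object_angles = tuple(float(a) for a in self.object_angles)
        if self.n_laps < 1:
            raise ConfigurationError("n_laps must be >= 1")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be > 0")
        if not 0.0 <= self.p_explore <= 1.0:
            raise ConfigurationError("p_explore must lie in [0, 1]")
        if self.maze_shape not in ("square", "circular"):
            raise ConfigurationError(f"unknown maze_shape {self.maze_shape!r}")
        angles = (self.reward_angle,) + self.object_angles
        for i in range(len(angles)):
            for j in range(i + 1, len(angles)):
                if circdist(angles[i], angles[j]) < 1e-9:
                    raise ConfigurationError(
                        "object angles must be distinct from each other "
                        "and from the reward angle")
        if self.inner_radius + self.track_width > self.outer_radius + 1e-9:
            raise GeometryError(
                f"track_width {self.track_width} cm does not fit between the "
                f"inner cylinder (r={self.inner_radius} cm) and the outer "
                f"wall (r={self.outer_radius} cm)")

    @property
    def inner_radius(self) -> float:
        return self.inner_diameter / 2.0

    @property
    def outer_radius(self) -> float:
        """Distance from center to the nearest outer-wall point (cm)."""
        return self.outer_size / 2.0

    @property
    def mid_radius(self) -> float:
        """Radius of the track midline (cm)."""
        return self.inner_radius + self.track_width / 2.0

    @property
    def center(self) -> tuple:
        return (self.outer_size / 2.0, self.outer_size / 2.0)


@dataclass
class PopulationConfig:
    """Composition and tuning of the simulated cell population.

    Activity is generated as sparse positive events (lognormal amplitudes)
    so traces look like deconvolved/inferred activity in arbitrary units.
    ``peak_rate`` is the expected trace value (arb. units) at the tuning
    peak; ``noise_rate`` the background expectation shared by all cells.
    Exploration-gated place cells (oePCs) carry their field a fixed lead
    distance before their object, matching the observed median activation
    lead of 0.78 s / 3.04 cm before object arrival.
    """

    n_cpc: int = 30
    n_oepc: int = 10
    n_ra: int = 10
    n_untuned: int = 50
    tuning_width: float = 0.35       # radians, Gaussian SD
    peak_rate: float = 6.0           # arb. units, expected activity at peak
    noise_rate: float = 0.1          # arb. units, background expectation
    event_amplitude_mean: float = 4.0  # arb. units per event
    event_amplitude_cv: float = 0.5
    oepc_lead_time: float = 0.78     # s
    oepc_lead_distance: float = 3.04  # cm
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cpc", "n_oepc", "n_ra", "n_untuned"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.tuning_width <= 0:
            raise ConfigurationError("tuning_width must be > 0")
        if not self.peak_rate > self.noise_rate >= 0:
            raise ConfigurationError("need peak_rate > noise_rate >= 0")

    @property
    def n_cells(self) -> int:
        return self.n_cpc + self.n_oepc + self.n_ra + self.n_untuned


@dataclass
class AnalysisConfig:
    """Statistical parameters of the analysis stages."""

    n_bins: int = 24
    si_z_threshold: float = 1.65
    n_si_shuffles: int = 100
    min_shift_frac: float = 0.05     # minimum circular-shift offset for SI null
    n_bout_shuffles: int = 1000
    bootstrap_criterion: float = 0.99
    min_activity: float = 2.0        # arb. units, oePC activity floor
    field_threshold: float = 0.2     # place-field rule: > 20% of cell max
    exclusion_sd: float = 2.0        # off-track / HD outlier band half-width
    recheck_alpha: float = 0.05      # Mann-Whitney retention level
    min_bouts: int = 3               # per label, oePC eligibility
    reward_window_bins: int = 3      # reward-proximal bins, centered
    ra_sd: float = 2.0
    speed_drop_enter: float = 2.0    # cm/s
    speed_drop_exit: float = 4.0     # cm/s
    n_decode_permutations: int = 100
    decode_percentile: float = 95.0
    n_corr_shuffles: int = 100
    corr_min_frames: int = 10
    lap_tolerance: float = np.pi / 12  # permitted net clockwise regression
    speed_smooth_window: int = 5
    seed: int = 0


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, with a single master seed."""

    session: SessionConfig = field(default_factory=SessionConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self):
        # the master seed propagates to every stage
        self.session.seed = int(self.seed)
        self.population.seed = int(self.seed) + 1
        self.analysis.seed = int(self.seed) + 2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["session"]["object_angles"] = list(self.session.object_angles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sess = {k: v for k, v in d.get("session", {}).items()
                if k in {f.name for f in dc_fields(SessionConfig)}}
        pop = {k: v for k, v in d.get("population", {}).items()
               if k in {f.name for f in dc_fields(PopulationConfig)}}
        ana = {k: v for k, v in d.get("analysis", {}).items()
               if k in {f.name for f in dc_fields(AnalysisConfig)}}
        return cls(session=SessionConfig(**sess),
                   population=PopulationConfig(**pop),
                   analysis=AnalysisConfig(**ana),
                   seed=int(d.get("seed", 0)))


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))
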