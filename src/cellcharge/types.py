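"""Domain types for the electrokinetic single-cell tracking pipeline.

Conventions used throughout the package
---------------------------------------
* Image coordinates: origin top-left, x to the right, y downward.
* The field axis unit vector points from anode to cathode (default +y).
  A cell with negative charge drifts antiparallel to this axis
  (electrophoresis of a negative particle is toward the anode).
* Positions are stored in micrometres unless a ``_px`` suffix says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CellModel",
    "MediumConditions",
    "FieldSchedule",
    "GroundTruthTrack",
    "SceneSpec",
    "SegmentationParams",
    "Detection",
    "TrackingParams",
    "Track",
    "TrackMetrics",
    "MsdResult",
    "FieldConditions",
    "ChargeEstimate",
]

#: Stokes-drag prefactor 6*pi, shared by the simulator and the inversion.
SIX_PI = 6.0 * np.pi

#: Paper-conditions defaults: dynamic viscosity of water and the effective
#: hydrodynamic radius of a ~1 um coccus.
DEFAULT_VISCOSITY_PA_S = 1.0e-3
DEFAULT_RADIUS_M = 5.0e-7


@dataclass(frozen=True)
class CellModel:
    """Ground-truth physical description of one simulated cell."""

    cell_id: int
    radius_m: float = DEFAULT_RADIUS_M
    charge_C: float = 0.0
    start_xy_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.radius_m > 0:
            raise ValueError(f"radius_m must be > 0, got {self.radius_m}")
        if not np.isfinite(self.charge_C):
            raise ValueError("charge_C must be finite")


@dataclass(frozen=True)
class MediumConditions:
    """Fluid properties of the suspension medium.

    The diffusion coefficient is supplied directly (a measured Brownian
    parameter) rather than derived from temperature via Stokes-Einstein.
    """

    viscosity_Pa_s: float = DEFAULT_VISCOSITY_PA_S
    conductivity_S_per_m: float = 1.337e-3
    pH: float = 5.8
    diffusion_um2_per_s: float = 0.16

    def __post_init__(self) -> None:
        if self.viscosity_Pa_s < 0 or self.conductivity_S_per_m < 0:
            raise ValueError("viscosity and conductivity must be >= 0")
        if self.diffusion_um2_per_s < 0:
            raise ValueError(
                f"diffusion coefficient must be >= 0, got {self.diffusion_um2_per_s}"
            )
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError(f"pH must lie in [0, 14], got {self.pH}")


@dataclass(frozen=True)
class FieldSchedule:
    """Uniform electric field magnitude, direction and on/off protocol.

    ``on_intervals`` are half-open [t_start, t_end) windows in seconds during
    which the field is applied; outside them the drift term vanishes.
    """

    E_V_per_m: float = 380.0
    axis_unit_vector: tuple[float, float] = (0.0, 1.0)
    on_intervals: tuple[tuple[float, float], ...] = ((0.0, np.inf),)

    def __post_init__(self) -> None:
        if self.E_V_per_m < 0:
            raise ValueError("field magnitude must be >= 0")
        norm = float(np.hypot(*self.axis_unit_vector))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"axis vector must have unit norm, got |v|={norm}")
        last_end = -np.inf
        for t0, t1 in self.on_intervals:
            if t0 < last_end or t1 <= t0:
                raise ValueError("on_intervals must be non-overlapping and increasing")
            last_end = t1

    def is_on(self, t: float | np.ndarray) -> np.ndarray:
        """Vectorised field-on indicator at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        on = np.zeros(t.shape, dtype=bool)
        for t0, t1 in self.on_intervals:
            on |= (t >= t0) & (t < t1)
        return on


@dataclass
class GroundTruthTrack:
    """True trajectory of one simulated cell (before rendering/detection)."""

    cell_id: int
    times_s: np.ndarray
    positions_um: np.ndarray  # shape (n, 2)
    drift_velocity_um_per_s: float  # signed field-axis drift while the field is on
    left_scene: bool = False

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if len(self.times_s) != len(self.positions_um):
            raise ValueError("times and positions must have equal length")


@dataclass(frozen=True)
class SceneSpec:
    """Imaging geometry and rendering parameters for the synthetic microscope."""

    width_px: int = 512
    height_px: int = 512
    pixel_scale_um: float = 0.093  # calibrated spatial resolution, um per pixel
    frame_interval_s: float = 0.2
    n_frames: int = 150
    cell_radius_px: float = 6.0
    background_level: int = 200
    cell_level: int = 60  # DIC cells appear dark on a light background
    psf_sigma_px: float = 1.0
    noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_scale_um <= 0:
            raise ValueError("pixel_scale_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_frames < 1 or self.width_px < 1 or self.height_px < 1:
            raise ValueError("scene dimensions must be positive")

    @property
    def width_um(self) -> float:
        return self.width_px * self.pixel_scale_um

    @property
    def height_um(self) -> float:
        return self.height_px * self.pixel_scale_um


@dataclass(frozen=True)
class SegmentationParams:
    """Preprocessing and contour-gating parameters.

    The area and enclosing-radius gates are strict inequalities: a contour is
    kept only if area > ``min_area_px2`` AND enclosing radius >
    ``min_enclosing_radius_px``.
    """

    blur_sigma_px: float = 2.0
    adaptive_block_px: int = 51
    adaptive_offset: float = 5.0
    morph_radius_px: int = 1
    min_area_px2: float = 50.0
    min_enclosing_radius_px: float = 4.0
    dark_cells: bool = True  # polarity: True = dark objects on light background

    def __post_init__(self) -> None:
        if self.adaptive_block_px < 3 or self.adaptive_block_px % 2 == 0:
            raise ValueError("adaptive_block_px must be odd and >= 3")


@dataclass(frozen=True)
class Detection:
    """One segmented cell in one frame."""

    frame_index: int
    centroid_px: tuple[float, float]  # (x, y), sub-pixel
    area_px2: float
    enclosing_radius_px: float


@dataclass(frozen=True)
class TrackingParams:
    """Frame-linking gates and track-quality filters."""

    max_assoc_dist_px: float = 100.0
    max_gap_frames: int = 2
    min_track_frames: int = 10
    max_area_change_frac: float = 0.5
    min_total_disp_px: float = 2.0
    subset_n: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "max_assoc_dist_px",
            "max_gap_frames",
            "min_track_frames",
            "max_area_change_frac",
            "min_total_disp_px",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.subset_n < 1:
            raise ValueError("subset_n must be >= 1")


@dataclass
class Track:
    """Time-ordered sequence of detections assigned to one cell identity."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    centroids_px: list[tuple[float, float]] = field(default_factory=list)
    areas_px2: list[float] = field(default_factory=list)
    status: str = "active"  # active | terminated | excluded
    exclusion_reason: str = "none"  # none | morphology | too_short | zero_velocity | left_focus
    misses: int = 0  # consecutive frames without a matched detection

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def centroid_array_px(self) -> np.ndarray:
        return np.asarray(self.centroids_px, dtype=float)

    def last_centroid(self) -> tuple[float, float]:
        return self.centroids_px[-1]


@dataclass
class TrackMetrics:
    """Per-track kinematics derived from centroid series."""

    track_id: int
    cum_disp_um: float
    inst_speeds_um_s: np.ndarray
    mean_speed_um_s: float
    mean_axis_vel_um_s: float
    n_steps: int


@dataclass
class MsdResult:
    """Ensemble-and-time-averaged MSD curve with its linear diffusion fit."""

    lags_s: np.ndarray
    msd_um2: np.ndarray
    slope_um2_s: float = np.nan
    intercept_um2: float = np.nan
    D_um2_s: float = np.nan
    r_squared: float = np.nan
    n_fit_points: int = 0


@dataclass(frozen=True)
class FieldConditions:
    """Electric-field conditions used for the charge inversion.

    ``E_V_per_m`` may be supplied directly, or derived as I/(sigma*A) from the
    current, conductivity and electrode cross-section.
    """

    E_V_per_m: float
    current_A: float | None = None
    conductivity_S_per_m: float | None = None
    electrode_cross_section_m2: float | None = None


@dataclass
class ChargeEstimate:
    """Per-cell effective surface charge with the inversion conditions used."""

    track_id: int
    mean_axis_vel_um_s: float
    q_C: float
    E_V_per_m: float
    viscosity_Pa_s: float
    radius_m: float
    n_steps: int = 0
    se_q_C: float = np.nan
    pH: float | None = None
    field_level: float | None = None
    growth_phase: str | None = None


def as_unit_vector(v: Sequence[float]) -> np.ndarray:
    """Validate and return ``v`` as a unit 2-vector (raises if not unit norm)."""
    v = np.asarray(v, dtype=float)
    if v.shape != (2,):
        raise ValueError("axis must be a 2-vector")
    norm = float(np.linalg.norm(v))
    if abs(norm - 1.0) > 1e-9:
        raise ValueError(f"axis must be a unit vector, got norm {norm}")
    return v
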