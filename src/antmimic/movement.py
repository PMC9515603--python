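"""Movement traits from centroid trajectories.

Four traits per 1-min recording, mirroring standard video-tracking output:

- mean velocity (cm/s): total path length over duration;
- locomotion (s, and proportion): cumulative time in the "moving" state,
  assigned by a speed hysteresis (enter above ``start_speed``, leave below
  ``stop_speed``) on a smoothed speed signal;
- mobility (%): share of centroid-stationary frames in which the body itself
  visibly moved (per-frame pixel-change fraction above a threshold);
- absolute angular velocity (deg/s): mean |heading change| per second over
  steps whose displacement is large enough to define a heading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class MotionParams:
    """Thresholds for state assignment; all speeds in cm/s.

    The tracking software the field uses does not expose its internal
    thresholds, so these are explicit and configurable.
    """

    start_speed: float = 0.50
    stop_speed: float = 0.25
    smooth_frames: int = 5
    min_displacement: float = 0.02  # cm; below this a heading is undefined
    mobility_threshold: float = 0.05  # body-change fraction

    def __post_init__(self) -> None:
        if self.stop_speed > self.start_speed:
            raise ValueError("stop_speed must be <= start_speed (hysteresis pair)")
        if min(self.start_speed, self.stop_speed, self.min_displacement) < 0:
            raise ValueError("speeds and displacements must be >= 0")


@dataclass
class Trajectory:
    """Time-stamped centroid path in cm, 30 fps nominal."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    body_change: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")
        if self.body_change is not None:
            self.body_change = np.asarray(self.body_change, dtype=float)
            if self.body_change.shape != self.t.shape:
                raise ValueError("body_change must align with frames")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def n_frames(self) -> int:
        return len(self.t)


@dataclass
class MovementTraits:
    mean_velocity: float  # cm/s
    locomotion_s: float  # s
    locomotion_prop: float  # of duration
    mobility_pct: float | None  # % of frames
    angular_velocity: float  # deg/s


def _step_speeds(traj: Trajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-step displacement (cm), dt (s) and speed (cm/s); length n-1."""
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    dt = np.diff(traj.t)
    disp = np.hypot(dx, dy)
    return disp, dt, disp / dt


def mean_velocity(traj: Trajectory) -> float:
    """Total path length divided by recording duration (cm/s)."""
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    disp, _, _ = _step_speeds(traj)
    return float(disp.sum() / traj.duration)


def _moving_state(traj: Trajectory, params: MotionParams) -> np.ndarray:
    """Boolean moving/not-moving per step from smoothed-speed hysteresis."""
    _, _, speed = _step_speeds(traj)
    w = max(1, int(params.smooth_frames))
    if w > 1:
        kernel = np.ones(w) / w
        speed = np.convolve(speed, kernel, mode="same")
    moving = np.empty(len(speed), dtype=bool)
    state = speed[0] > params.start_speed
    for i, s in enumerate(speed):
        if state:
            if s < params.stop_speed:
                state = False
        elif s > params.start_speed:
            state = True
        moving[i] = state
    return moving


def locomotion(traj: Trajectory, params: MotionParams | None = None) -> tuple[float, float]:
    """Cumulative duration of moving (s) and proportion of total duration."""
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    params = params or MotionParams()
    moving = _moving_state(traj, params)
    dt = np.diff(traj.t)
    seconds = float(dt[moving].sum())
    return seconds, seconds / traj.duration


def angular_velocity(traj: Trajectory, params: MotionParams | None = None) -> float:
    """Mean absolute heading change per unit time (deg/s).

    Headings come from displacement vectors; steps below ``min_displacement``
    carry no heading and are skipped (the denominator uses valid transitions
    only).  Returns 0 with a warning if no valid transition exists.
    """
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames")
    params = params or MotionParams()
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    dt = np.diff(traj.t)
    disp = np.hypot(dx, dy)
    valid = disp > params.min_displacement
    idx = np.flatnonzero(valid)
    if len(idx) < 2:
        logger.warning("no valid heading transition; angular velocity set to 0")
        return 0.0
    headings = np.arctan2(dy[idx], dx[idx])
    dtheta = np.diff(headings)
    # wrap to (-pi, pi]
    dtheta = (dtheta + np.pi) % (2 * np.pi) - np.pi
    # time between successive valid headings: midpoint-to-midpoint of steps
    t_mid = traj.t[idx] + dt[idx] / 2
    step_dt = np.diff(t_mid)
    rates = np.abs(np.degrees(dtheta)) / step_dt
    return float(rates.mean())


def mobility(traj: Trajectory, params: MotionParams | None = None) -> float:
    """Percent of frames in which the body moved while the centroid was stationary."""
    params = params or MotionParams()
    if traj.body_change is None:
        raise ValueError(
            "trajectory has no body_change channel; supply per-frame pixel-change "
            "fractions to compute mobility"
        )
    moving = _moving_state(traj, params)
    # align step states to frames: frame i takes the state of step i-1, frame 0 of step 0
    frame_moving = np.concatenate([[moving[0]], moving]) if len(moving) else np.zeros(1, bool)
    stationary = ~frame_moving
    flagged = stationary & (traj.body_change > params.mobility_threshold)
    return float(100.0 * flagged.sum() / traj.n_frames)


def movement_traits(traj: Trajectory, params: MotionParams | None = None) -> MovementTraits:
    """All four movement traits for one recording."""
    params = params or MotionParams()
    loco_s, loco_p = locomotion(traj, params)
    mob = mobility(traj, params) if traj.body_change is not None else None
    return MovementTraits(
        mean_velocity=mean_velocity(traj),
        locomotion_s=loco_s,
        locomotion_prop=loco_p,
        mobility_pct=mob,
        angular_velocity=angular_velocity(traj, params),
    )
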