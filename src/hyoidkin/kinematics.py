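"""Time-normalized hyoid kinematics and discrete summary parameters.

Each swallow is remapped onto a common 0–100 percentile grid so that
subjects with different swallow durations are comparable pointwise.  On that
grid the module computes displacement, velocity by the symmetric difference
quotient (units mm per percentile), and the direction angle of the motion
vector relative to the anterior (+x) axis.  Discrete summaries — signed
displacement/velocity extrema with their times, the mean early-phase
direction angle, and total swallow duration — are the classical per-subject
kinematic parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import AnatomicalTrajectory

__all__ = [
    "KinematicProfile",
    "SummaryParameters",
    "SwallowDetectionError",
    "normalize_time",
    "detect_swallow_window",
    "compute_velocity",
    "compute_direction_angles",
    "mean_early_phase_angle",
    "summarize",
    "continuous_angle",
]

#: below this speed (mm/percentile) the motion has no meaningful direction
ANGLE_VELOCITY_FLOOR = 1e-6


class SwallowDetectionError(RuntimeError):
    """No hyoid motion above threshold; the window must be set manually."""


@dataclass
class KinematicProfile:
    """Displacement, velocity and direction angle on the percentile grid.

    ``angle`` is NaN wherever the velocity magnitude is below the floor
    (``angle_defined`` False); a zero-velocity sample has no direction.
    """

    grid: np.ndarray
    disp_x: np.ndarray
    disp_y: np.ndarray
    duration_s: float
    vel_x: np.ndarray | None = None
    vel_y: np.ndarray | None = None
    angle: np.ndarray | None = None
    angle_defined: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.disp_x = np.asarray(self.disp_x, dtype=float)
        self.disp_y = np.asarray(self.disp_y, dtype=float)
        m = len(self.grid)
        if len(self.disp_x) != m or len(self.disp_y) != m:
            raise ValueError("displacement arrays must match the grid length")
        if m < 2 or not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if not (self.grid[0] == 0.0 and self.grid[-1] == 100.0):
            raise ValueError("grid must span 0..100")


@dataclass
class SummaryParameters:
    """Per-subject discrete kinematic parameters.

    Signed convention: forward/upward extrema are maxima (≥ 0 because the
    profile starts at the origin), backward extrema are minima (≤ 0).
    Times are percentiles of normalized swallow time; velocities are in
    mm/percentile.
    """

    max_backward_x: float
    max_forward_x: float
    max_upward_y: float
    time_max_backward_x: float
    time_max_forward_x: float
    time_max_upward_y: float
    max_backward_vx: float
    max_forward_vx: float
    max_upward_vy: float
    time_max_backward_vx: float
    time_max_forward_vx: float
    time_max_upward_vy: float
    mean_early_angle: float
    duration_s: float
    subject_id: str = ""


def normalize_time(
    traj: AnatomicalTrajectory,
    window: tuple[int, int],
    n_grid: int = 101,
) -> KinematicProfile:
    """Resample the windowed trajectory onto the uniform percentile grid.

    The physical time between the window's start and end frames is mapped
    linearly to [0, 100] and each coordinate is linearly interpolated onto
    ``n_grid`` evenly spaced percentile points.  The trajectory must already
    be rebased at the start frame, so displacement at percentile 0 is (0, 0).
    """
    start, end = int(window[0]), int(window[1])
    n = len(traj)
    if not (0 <= start < end < n):
        raise IndexError(f"window {window} out of range for {n} frames")
    if end - start + 1 < 4:
        raise ValueError("swallow window must span at least 4 frames")
    if not traj.rebased:
        raise ValueError("trajectory must be rebased to the swallow start point")
    t = traj.time[start : end + 1]
    if not np.all(np.diff(t) > 0):
        raise ValueError("time must be strictly increasing inside the window")
    pos = traj.position_mm[start : end + 1]
    if np.any(np.abs(pos[0]) > 1e-9):
        raise ValueError("trajectory is not rebased at the window start frame")
    duration = float(t[-1] - t[0])
    pct = 100.0 * (t - t[0]) / duration
    pct[-1] = 100.0  # guard against round-off at the endpoint
    grid = np.linspace(0.0, 100.0, n_grid)
    disp_x = np.interp(grid, pct, pos[:, 0])
    disp_y = np.interp(grid, pct, pos[:, 1])
    return KinematicProfile(
        grid=grid,
        disp_x=disp_x,
        disp_y=disp_y,
        duration_s=duration,
        subject_id=traj.subject_id,
    )


def _robust_speed(time: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Per-interval speed (mm/s) that tolerates landmark jitter.

    Positions are smoothed with a short centered moving average and speeds
    taken over a two-interval baseline, which suppresses frame-to-frame
    annotation noise without displacing the onset by more than ~1 frame.
    """
    n = len(pos)
    win = min(3, n)
    kernel = np.ones(win) / win
    sm = np.column_stack(
        [np.convolve(np.pad(pos[:, j], win // 2, mode="edge"), kernel, "valid")
         for j in range(2)]
    )
    lag = min(2, n - 1)
    disp = np.linalg.norm(sm[lag:] - sm[:-lag], axis=1)
    dt = time[lag:] - time[:-lag]
    wide = disp / dt  # speed centered between i and i+lag
    # map back onto the n-1 frame intervals
    speed = np.empty(n - 1)
    for i in range(n - 1):
        k = min(max(i - (lag - 1) // 2, 0), len(wide) - 1)
        speed[i] = wide[k]
    return speed


def detect_swallow_window(
    traj: AnatomicalTrajectory,
    speed_threshold_mm_s: float = 5.0,
    dwell_frames: int = 3,
    start_tol_mm: float = 0.3,
    manual_window: tuple[int, int] | None = None,
) -> tuple[int, int]:
    """Locate the swallow on an anatomical trajectory.

    The start is the hyoid's lowest pre-peak position: the last frame before
    the vertical peak whose height is within ``start_tol_mm`` of the pre-peak
    minimum (so a quiescent lead-in collapses onto the moment motion begins).
    If the vertical peak is degenerate the first frame whose frame-to-frame
    speed exceeds ``speed_threshold_mm_s`` is used instead.  The end is the
    first post-peak frame after which the speed stays below threshold for
    ``dwell_frames`` consecutive intervals.  An explicitly supplied
    ``manual_window`` always wins.
    """
    if manual_window is not None:
        start, end = int(manual_window[0]), int(manual_window[1])
        if not (0 <= start < end < len(traj)):
            raise IndexError(f"manual window {manual_window} out of range")
        return (start, end)

    n = len(traj)
    if n < 4:
        raise SwallowDetectionError("trajectory too short to contain a swallow")
    pos = traj.position_mm
    speed = _robust_speed(traj.time, pos)
    moving = speed > speed_threshold_mm_s
    if not np.any(moving):
        raise SwallowDetectionError(
            "no hyoid motion above threshold; annotate the window manually"
        )

    # onset candidate: first clearly moving frame, walked back to where the
    # speed last sat near the quiescent floor (motion builds up gradually,
    # so thresholding alone starts a couple of frames late)
    onset = int(np.argmax(moving))
    while onset > 0 and speed[onset - 1] > 0.4 * speed_threshold_mm_s:
        onset -= 1

    y = pos[:, 1]
    peak = int(np.argmax(y))
    if peak == 0:
        start = onset
    else:
        pre = y[: peak + 1]
        low = pre <= pre.min() + start_tol_mm
        start = min(int(np.nonzero(low)[0][-1]), onset)

    # end: first post-peak quiescent stretch of dwell_frames intervals
    end = n - 1
    quiet = ~moving
    for i in range(max(peak, start + 1), n - 1):
        run = quiet[i : i + dwell_frames]
        if len(run) > 0 and np.all(run):
            end = i
            break
    if end <= start:
        end = n - 1
    # a swallow needs a few frames even when motion is marginal
    if end - start < 3:
        end = min(n - 1, start + 3)
        start = max(0, end - 3)
    return (start, end)


def compute_velocity(profile: KinematicProfile) -> KinematicProfile:
    """Fill velocities by the symmetric difference quotient.

    Interior points use v(t) = (d(t+h) − d(t−h)) / 2h on the percentile
    grid (exact for quadratics); the endpoints fall back to one-sided
    differences.  Units are mm per percentile.
    """
    h = np.diff(profile.grid)
    if not np.allclose(h, h[0]):
        raise ValueError("velocity requires a uniformly spaced grid")
    step = h[0]

    def sdq(d: np.ndarray) -> np.ndarray:
        v = np.empty_like(d)
        v[1:-1] = (d[2:] - d[:-2]) / (2.0 * step)
        v[0] = (d[1] - d[0]) / step
        v[-1] = (d[-1] - d[-2]) / step
        return v

    profile.vel_x = sdq(profile.disp_x)
    profile.vel_y = sdq(profile.disp_y)
    return profile


def compute_direction_angles(
    profile: KinematicProfile, velocity_floor: float = ANGLE_VELOCITY_FLOOR
) -> KinematicProfile:
    """Fill the hyoid direction angle in degrees on [0, 360).

    The angle is the two-argument arctangent of the velocity vector measured
    from the positive horizontal (anterior) axis: 0° is straight forward,
    90° straight up, 135° backward-upward.  Samples slower than
    ``velocity_floor`` get no angle (NaN, ``angle_defined`` False).
    """
    if profile.vel_x is None or profile.vel_y is None:
        raise ValueError("velocities must be computed before direction angles")
    speed = np.hypot(profile.vel_x, profile.vel_y)
    defined = speed >= velocity_floor
    angle = np.degrees(np.arctan2(profile.vel_y, profile.vel_x)) % 360.0
    angle[~defined] = np.nan
    profile.angle = angle
    profile.angle_defined = defined
    return profile


def mean_early_phase_angle(
    profile: KinematicProfile,
    lo: float = 5.0,
    hi: float = 20.0,
    circular: bool = False,
) -> float:
    """Mean of defined direction angles on grid points in [lo, hi].

    The 5th–20th percentile window is the early phase of the swallow, where
    the initial backward-upward hyoid motion occurs (angles below the 5th
    percentile are too variable to be informative).  The default is the
    arithmetic mean — early-phase motion is confined to the 90–180° quadrant
    where arithmetic and circular means agree; ``circular=True`` uses the
    circular mean (result mapped to [0, 360)) for data that straddle the
    0/360 seam.
    """
    if profile.angle is None:
        raise ValueError("direction angles must be computed first")
    sel = (profile.grid >= lo) & (profile.grid <= hi)
    vals = profile.angle[sel]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError(
            f"no defined direction angles in the {lo}-{hi} percentile window"
        )
    if circular:
        rad = np.radians(vals)
        return float(
            np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))
            % 360.0
        )
    return float(np.mean(vals))


def continuous_angle(profile: KinematicProfile) -> np.ndarray:
    """Direction angle unwrapped into a continuous curve (degrees).

    The raw angle lives on [0, 360) and jumps by ~360° when the motion
    vector crosses the +x axis, which would wreck smoothing and functional
    regression.  This fills undefined samples by linear interpolation and
    unwraps the result; values may leave [0, 360).
    """
    if profile.angle is None:
        raise ValueError("direction angles must be computed first")
    ang = profile.angle.copy()
    bad = np.isnan(ang)
    if bad.all():
        raise ValueError("all direction angles are undefined")
    if bad.any():
        ang[bad] = np.interp(
            profile.grid[bad], profile.grid[~bad], ang[~bad]
        )
    return np.degrees(np.unwrap(np.radians(ang)))


def _signed_extrema(values: np.ndarray, grid: np.ndarray) -> tuple[float, float, float, float]:
    """(min, time-of-min, max, time-of-max); ties broken toward earliest time."""
    imin = int(np.argmin(values))
    imax = int(np.argmax(values))
    return (
        float(values[imin]),
        float(grid[imin]),
        float(values[imax]),
        float(grid[imax]),
    )


def summarize(profile: KinematicProfile) -> SummaryParameters:
    """Extract the discrete summary parameters from a complete profile."""
    if profile.vel_x is None or profile.angle is None:
        raise ValueError("profile must have velocities and angles computed")
    bx, t_bx, fx, t_fx = _signed_extrema(profile.disp_x, profile.grid)
    _, _, uy, t_uy = _signed_extrema(profile.disp_y, profile.grid)
    bvx, t_bvx, fvx, t_fvx = _signed_extrema(profile.vel_x, profile.grid)
    _, _, uvy, t_uvy = _signed_extrema(profile.vel_y, profile.grid)
    return SummaryParameters(
        max_backward_x=bx,
        max_forward_x=fx,
        max_upward_y=uy,
        time_max_backward_x=t_bx,
        time_max_forward_x=t_fx,
        time_max_upward_y=t_uy,
        max_backward_vx=bvx,
        max_forward_vx=fvx,
        max_upward_vy=uvy,
        time_max_backward_vx=t_bvx,
        time_max_forward_vx=t_fvx,
        time_max_upward_vy=t_uvy,
        mean_early_angle=mean_early_phase_angle(profile),
        duration_s=profile.duration_s,
        subject_id=profile.subject_id,
    )
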