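"""Synthetic two-group VFSS landmark cohorts with known ground truth.

Real hyoid trajectories trace a loop: an early backward-upward pull, a
dominant forward-upward excursion opening the upper esophageal sphincter,
and a return toward the start.  The generator models the anatomical-frame
displacement as three smooth unimodal bumps,

    x(t) = −B·g(t; t_b, w_b) + F·g(t; t_f, w_f)
    y(t) =  U·g(t; t_u, w_u),

on normalized time t ∈ [0, 100], where g is a truncated Gaussian bump
vanishing at both endpoints with g(center) = 1.  Per-subject amplitudes
(B, F, U), bump timings and swallow duration are drawn from group-specific
normal distributions truncated at zero.  Group structure follows the
published cohort moments for post-stroke dysphagia patients with good and
poor swallowing prognosis: reduced forward amplitude in the poor group,
slightly larger upward amplitude, and a backward amplitude scaled down
relative to vertical so the early-phase direction angle is lower (more
vertical initial motion).

The rendered observation is what landmark tracking software would emit:
pixel coordinates of the hyoid and of the C2/C4 anteroinferior vertices at
30 frames/s (image-down y axis), with a quiescent lead-in and tail, a slow
rigid whole-neck drift (rotation + translation random walk) applied jointly
to all landmarks, independent Gaussian pixel noise per landmark coordinate,
and a coin calibration value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import LandmarkFrameSeries, ScaleCalibration

__all__ = [
    "SyntheticCohortConfig",
    "SubjectGroundTruth",
    "template_trajectory",
    "generate_subject",
    "generate_cohort",
]

_GROUPS = ("good", "poor")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full parameterization of the synthetic cohort.

    Two-element tuples are (good, poor) group values.  Amplitudes are in mm,
    durations in seconds, bump centers/widths in normalized-time percentiles.
    Defaults reproduce the published cohort moments (forward amplitude
    12.43 ± 4.81 vs 9.22 ± 3.95 mm, upward 15.37 ± 7.14 vs 16.81 ± 7.10 mm,
    duration 1.76 ± 0.45 vs 1.89 ± 0.47 s at 30 frames/s); the poor group's
    backward amplitude is scaled by ``backward_scale_poor``, calibrated so
    the early-phase direction angle gap is about 23 degrees.
    """

    n_good: int = 18
    n_poor: int = 18
    fps: float = 30.0
    duration_mean: tuple[float, float] = (1.76, 1.89)
    duration_sd: tuple[float, float] = (0.45, 0.47)
    forward_mean: tuple[float, float] = (12.43, 9.22)
    forward_sd: tuple[float, float] = (4.81, 3.95)
    backward_mean: tuple[float, float] = (3.5, 3.5)
    backward_sd: tuple[float, float] = (2.6, 2.6)
    backward_scale_poor: float = 0.08
    upward_mean: tuple[float, float] = (15.37, 16.81)
    upward_sd: tuple[float, float] = (7.14, 7.10)
    # bump centers sit inside the published time-to-maximum ranges
    t_backward: float = 20.0
    t_forward: float = 49.0
    t_upward: float = 34.0
    w_backward: float = 8.0
    w_forward: float = 12.5
    w_upward: float = 15.0
    timing_sd: tuple[float, float, float] = (3.0, 5.0, 6.0)
    pixel_noise_sd: float = 0.15
    drift_rot_sd: float = 0.002
    drift_trans_sd: float = 0.5
    mm_per_px: float = 0.5
    coin_mm: float = 23.5
    lead_in_s: float = 0.3
    tail_s: float = 0.3
    min_duration_s: float = 0.8
    c2c4_mm: float = 38.0
    hyoid_rest_mm: tuple[float, float] = (30.0, 12.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_good < 2 or self.n_poor < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for name in ("duration_mean", "forward_mean", "backward_mean", "upward_mean"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} entries must be positive")
        for c in (self.t_backward, self.t_forward, self.t_upward):
            if not 0.0 < c < 100.0:
                raise ValueError("bump centers must lie strictly inside (0, 100)")

    @property
    def coin_px(self) -> float:
        return self.coin_mm / self.mm_per_px

    @property
    def calibration(self) -> ScaleCalibration:
        return ScaleCalibration(coin_px=self.coin_px, coin_mm=self.coin_mm)


@dataclass
class SubjectGroundTruth:
    """Drawn parameters and noise-free truth for one synthetic subject."""

    subject_id: str
    group: str
    forward: float
    backward: float
    upward: float
    duration_s: float
    t_backward: float
    t_forward: float
    t_upward: float
    w_backward: float
    w_forward: float
    w_upward: float
    window: tuple[int, int]  # true (start_frame, end_frame)
    grid: np.ndarray = field(default_factory=lambda: np.linspace(0, 100, 101))
    true_disp_x: np.ndarray | None = None
    true_disp_y: np.ndarray | None = None

    def displacement(self, t: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
        """Noise-free displacement curves at normalized times t."""
        return template_trajectory(
            self.forward,
            self.backward,
            self.upward,
            timings=(self.t_backward, self.t_forward, self.t_upward),
            widths=(self.w_backward, self.w_forward, self.w_upward),
            t=t,
        )

    def forward_bump_support(self, level: float = 0.5) -> tuple[float, float]:
        """Normalized-time interval where the forward bump exceeds ``level``
        of its maximum (the half-maximum support by default)."""
        t = np.linspace(0.0, 100.0, 1001)
        g = _bump(t, self.t_forward, self.w_forward)
        above = np.nonzero(g >= level * g.max())[0]
        return (float(t[above[0]]), float(t[above[-1]]))


def _bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Truncated-Gaussian bump on [0, 100]: zero at both endpoints, 1 at center.

    A Gaussian has small but nonzero tails at the domain ends; subtracting
    the chord through its endpoint values zeroes them while keeping the shape
    smooth, and the result is renormalized to equal 1 at the center.
    """
    if not 0.0 < center < 100.0:
        raise ValueError(f"bump center {center} outside (0, 100)")
    if width <= 0:
        raise ValueError("bump width must be positive")
    t = np.asarray(t, dtype=float)
    phi = np.exp(-((t - center) ** 2) / (2.0 * width**2))
    p0 = np.exp(-(center**2) / (2.0 * width**2))
    p1 = np.exp(-((100.0 - center) ** 2) / (2.0 * width**2))
    chord = p0 + (p1 - p0) * t / 100.0
    norm = 1.0 - (p0 + (p1 - p0) * center / 100.0)
    return (phi - chord) / norm


def template_trajectory(
    F: float,
    B: float,
    U: float,
    timings: tuple[float, float, float] = (20.0, 49.0, 34.0),
    widths: tuple[float, float, float] = (8.0, 12.5, 15.0),
    t: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free template displacement (x, y) in mm at normalized times t.

    ``timings``/``widths`` are (backward, forward, upward) bump centers and
    widths in percentiles.  x is anterior-positive, y superior-positive; the
    curve starts and ends at the origin.
    """
    if F < 0 or B < 0 or U < 0:
        raise ValueError("amplitudes must be nonnegative")
    if t is None:
        t = np.linspace(0.0, 100.0, 101)
    t = np.asarray(t, dtype=float)
    t_b, t_f, t_u = timings
    w_b, w_f, w_u = widths
    x = np.zeros_like(t)
    y = np.zeros_like(t)
    if B > 0:
        x = x - B * _bump(t, t_b, w_b)
    if F > 0:
        x = x + F * _bump(t, t_f, w_f)
    if U > 0:
        y = U * _bump(t, t_u, w_u)
    return x, y


def _draw_positive(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at zero (simple rejection; mean must be > 0)."""
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise RuntimeError("truncated-normal rejection failed; check mean/sd")


def generate_subject(
    cfg: SyntheticCohortConfig,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "s000",
) -> tuple[LandmarkFrameSeries, SubjectGroundTruth]:
    """Draw one subject and render its landmark pixel time series."""
    gi = _GROUPS.index(group)
    duration = max(
        cfg.min_duration_s, _draw_positive(rng, cfg.duration_mean[gi], cfg.duration_sd[gi])
    )
    F = _draw_positive(rng, cfg.forward_mean[gi], cfg.forward_sd[gi])
    B = _draw_positive(rng, cfg.backward_mean[gi], cfg.backward_sd[gi])
    U = _draw_positive(rng, cfg.upward_mean[gi], cfg.upward_sd[gi])
    if group == "poor":
        B *= cfg.backward_scale_poor
    sd_b, sd_f, sd_u = cfg.timing_sd
    t_b = float(np.clip(rng.normal(cfg.t_backward, sd_b), 5.0, 30.0))
    t_u = float(np.clip(rng.normal(cfg.t_upward, sd_u), 20.0, 60.0))
    t_f = float(np.clip(rng.normal(cfg.t_forward, sd_f), max(t_b + 10.0, 35.0), 80.0))

    n_frames = int(round((cfg.lead_in_s + duration + cfg.tail_s) * cfg.fps)) + 1
    times = np.arange(n_frames) / cfg.fps
    k_start = int(round(cfg.lead_in_s * cfg.fps))
    k_end = int(round((cfg.lead_in_s + duration) * cfg.fps))
    k_end = min(k_end, n_frames - 1)

    # motion span quantized to the frame grid, so the swallow occupies the
    # frames [k_start, k_end] exactly and the drawn duration rounds to it
    span = times[k_end] - times[k_start]
    pct = 100.0 * np.clip((times - times[k_start]) / span, 0.0, 1.0)
    timings = (t_b, t_f, t_u)
    widths = (cfg.w_backward, cfg.w_forward, cfg.w_upward)
    dx, dy = template_trajectory(F, B, U, timings=timings, widths=widths, t=pct)

    # scene in mm: C4 at origin, C2 straight above, hyoid anterior-superior
    hyoid = np.column_stack(
        [cfg.hyoid_rest_mm[0] + dx, cfg.hyoid_rest_mm[1] + dy]
    )
    c2 = np.tile([0.0, cfg.c2c4_mm], (n_frames, 1))
    c4 = np.zeros((n_frames, 2))

    # slow rigid neck drift, applied jointly to every landmark
    theta = np.cumsum(rng.normal(0.0, cfg.drift_rot_sd, n_frames))
    shift = np.cumsum(
        rng.normal(0.0, cfg.drift_trans_sd * cfg.mm_per_px, (n_frames, 2)), axis=0
    )
    cos, sin = np.cos(theta), np.sin(theta)

    def drifted(pts: np.ndarray) -> np.ndarray:
        xr = cos * pts[:, 0] - sin * pts[:, 1] + shift[:, 0]
        yr = sin * pts[:, 0] + cos * pts[:, 1] + shift[:, 1]
        return np.column_stack([xr, yr])

    offset = np.array([256.0, 384.0])  # image placement, px

    def to_px(pts_mm: np.ndarray) -> np.ndarray:
        px = pts_mm / cfg.mm_per_px
        out = np.column_stack([offset[0] + px[:, 0], offset[1] - px[:, 1]])
        return out + rng.normal(0.0, cfg.pixel_noise_sd, out.shape)

    series = LandmarkFrameSeries(
        frame_index=np.arange(n_frames),
        time=times,
        hyoid_px=to_px(drifted(hyoid)),
        c2_px=to_px(drifted(c2)),
        c4_px=to_px(drifted(c4)),
        y_axis_convention="image-down",
        subject_id=subject_id,
    )
    grid = np.linspace(0.0, 100.0, 101)
    gx, gy = template_trajectory(F, B, U, timings=timings, widths=widths, t=grid)
    truth = SubjectGroundTruth(
        subject_id=subject_id,
        group=group,
        forward=F,
        backward=B,
        upward=U,
        duration_s=float(times[k_end] - times[k_start]),
        t_backward=t_b,
        t_forward=t_f,
        t_upward=t_u,
        w_backward=cfg.w_backward,
        w_forward=cfg.w_forward,
        w_upward=cfg.w_upward,
        window=(k_start, k_end),
        grid=grid,
        true_disp_x=gx,
        true_disp_y=gy,
    )
    return series, truth


def generate_cohort(
    cfg: SyntheticCohortConfig,
    seed: int | None = None,
) -> tuple[list[LandmarkFrameSeries], list[SubjectGroundTruth], list[str]]:
    """Generate the full two-group cohort, deterministic under ``seed``.

    Returns (landmark series, ground truths, group labels), good-prognosis
    subjects first.  ``seed`` overrides ``cfg.seed`` when given.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    series_list: list[LandmarkFrameSeries] = []
    truths: list[SubjectGroundTruth] = []
    labels: list[str] = []
    counter = 0
    for group, n in (("good", cfg.n_good), ("poor", cfg.n_poor)):
        for _ in range(n):
            sid = f"s{counter:03d}_{group}"
            s, gt = generate_subject(cfg, group, rng, subject_id=sid)
            series_list.append(s)
            truths.append(gt)
            labels.append(group)
            counter += 1
    return series_list, truths, labels
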