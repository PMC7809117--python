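"""Anatomical coordinate normalization for lateral videofluoroscopic landmarks.

Raw landmark positions come out of tracking software as image pixel
coordinates.  Before hyoid trajectories from different frames (and different
patients) can be compared, three things must be removed:

* whole-neck motion, by re-expressing the hyoid in a vertebral reference
  frame with origin at the anteroinferior vertex of C4 and vertical axis
  through the anteroinferior vertex of C2;
* the unknown image magnification, using a coin of known physical diameter
  visible in the field of view;
* the arbitrary resting position, by shifting the trajectory so the hyoid
  sits at (0, 0) at the start of the swallow.

The anatomical frame is right-handed with x anterior-positive and
y superior-positive, in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "YAxisConvention",
    "ScaleCalibration",
    "LandmarkFrameSeries",
    "AnatomicalTrajectory",
    "FrameTransform",
    "CalibrationError",
    "DegenerateAxisError",
    "AmbiguousOrientationError",
    "compute_scale_factor",
    "build_frame_transform",
    "to_anatomical",
    "rebase_to_start",
]

YAxisConvention = Literal["image-down", "math-up"]


class CalibrationError(ValueError):
    """Raised for an unusable scale calibration (non-positive coin size)."""


class DegenerateAxisError(ValueError):
    """Raised when the C2 and C4 landmarks coincide and define no axis."""


class AmbiguousOrientationError(ValueError):
    """Raised when the anterior hint lies exactly on the vertebral axis."""


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-millimetre scale from a reference coin.

    Parameters
    ----------
    coin_px : float
        Measured coin diameter in pixels.
    coin_mm : float
        Physical coin diameter in millimetres (default 23.5 mm).
    """

    coin_px: float
    coin_mm: float = 23.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.coin_px) or self.coin_px <= 0:
            raise CalibrationError(f"coin_px must be > 0, got {self.coin_px}")
        if not np.isfinite(self.coin_mm) or self.coin_mm <= 0:
            raise CalibrationError(f"coin_mm must be > 0, got {self.coin_mm}")

    @property
    def mm_per_px(self) -> float:
        return self.coin_mm / self.coin_px


def compute_scale_factor(cal: ScaleCalibration) -> float:
    """Millimetres per pixel implied by the coin calibration."""
    return cal.mm_per_px


@dataclass
class LandmarkFrameSeries:
    """Per-frame pixel coordinates of the tracked landmarks for one swallow.

    Attributes
    ----------
    frame_index : (n,) int array
    time : (n,) float array, seconds, strictly increasing
    hyoid_px, c2_px, c4_px : (n, 2) float arrays
        Pixel coordinates of the hyoid body and the anteroinferior vertices
        of C2 and C4.
    y_axis_convention : {"image-down", "math-up"}
        Whether the pixel y axis points down the image (the usual raster
        convention) or up.
    subject_id : str
        Optional identifier carried through the pipeline.
    """

    frame_index: np.ndarray
    time: np.ndarray
    hyoid_px: np.ndarray
    c2_px: np.ndarray
    c4_px: np.ndarray
    y_axis_convention: YAxisConvention = "image-down"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.time = np.asarray(self.time, dtype=float)
        for name in ("hyoid_px", "c2_px", "c4_px"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{name} must be an (n, 2) array")
            setattr(self, name, arr)
        n = len(self.time)
        if not (
            len(self.frame_index) == n
            and all(len(getattr(self, a)) == n for a in ("hyoid_px", "c2_px", "c4_px"))
        ):
            raise ValueError("all per-frame sequences must have equal length")
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if any(
            not np.all(np.isfinite(getattr(self, a)))
            for a in ("hyoid_px", "c2_px", "c4_px")
        ):
            raise ValueError("landmark coordinates must be finite (no missing frames)")
        if self.y_axis_convention not in ("image-down", "math-up"):
            raise ValueError(f"unknown y_axis_convention {self.y_axis_convention!r}")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class AnatomicalTrajectory:
    """Hyoid trajectory in the C2–C4 anatomical frame, in millimetres.

    x is anterior-positive, y superior-positive.  ``rebased`` records whether
    the trajectory has been shifted so the swallow start point is the origin.
    """

    time: np.ndarray
    position_mm: np.ndarray
    rebased: bool = False
    start_frame: int | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        if self.position_mm.ndim != 2 or self.position_mm.shape[1] != 2:
            raise ValueError("position_mm must be an (n, 2) array")
        if len(self.time) != len(self.position_mm):
            raise ValueError("time and position_mm must have equal length")
        if not np.all(np.isfinite(self.position_mm)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class FrameTransform:
    """Rigid map from (convention-resolved) pixel space to the vertebral frame.

    Maps a math-up pixel point p to ``rotation @ p + translation`` so that C4
    lands on the origin and C2 on the positive y axis.  Distances are
    preserved; output units are still pixels.
    """

    rotation: np.ndarray  # (2, 2) orthonormal
    translation: np.ndarray  # (2,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out


def _resolve_convention(points: np.ndarray, convention: YAxisConvention) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if convention == "image-down":
        pts = pts * np.array([1.0, -1.0])
    return pts


def build_frame_transform(
    c2: Sequence[float],
    c4: Sequence[float],
    anterior_hint: Sequence[float],
    y_axis_convention: YAxisConvention = "math-up",
) -> FrameTransform:
    """Rigid transform of the vertebral frame for one image.

    The transform sends the C4 anteroinferior vertex to the origin and the C2
    vertex to (0, ‖c2 − c4‖); the +x direction is the perpendicular pointing
    toward ``anterior_hint`` (typically the hyoid, which lies anterior to the
    vertebral column on a lateral view).

    Raises
    ------
    DegenerateAxisError
        If c2 and c4 coincide.
    AmbiguousOrientationError
        If the hint lies exactly on the C2–C4 axis.
    """
    c2r = _resolve_convention(np.asarray(c2, float), y_axis_convention)
    c4r = _resolve_convention(np.asarray(c4, float), y_axis_convention)
    hint = _resolve_convention(np.asarray(anterior_hint, float), y_axis_convention)

    axis = c2r - c4r
    d = float(np.hypot(*axis))
    if d == 0.0:
        raise DegenerateAxisError("C2 and C4 landmarks coincide; no vertebral axis")
    u_y = axis / d
    u_x = np.array([u_y[1], -u_y[0]])  # one of the two perpendiculars
    side = float(np.dot(hint - c4r, u_x))
    if side == 0.0:
        raise AmbiguousOrientationError(
            "anterior hint lies on the C2-C4 axis; cannot orient the x axis"
        )
    if side < 0:
        u_x = -u_x
    rotation = np.stack([u_x, u_y])  # rows: new basis in old coordinates
    translation = -rotation @ c4r
    return FrameTransform(rotation=rotation, translation=translation)


def to_anatomical(
    series: LandmarkFrameSeries,
    cal: ScaleCalibration,
    mode: Literal["per-frame", "fixed"] = "per-frame",
    reference_frame: int = 0,
) -> AnatomicalTrajectory:
    """Express the hyoid in the C2–C4 frame, scaled to millimetres.

    With ``mode="per-frame"`` (default) the vertebral transform is rebuilt
    from each frame's own C2/C4 landmarks, so rigid neck motion during the
    swallow cancels exactly.  ``mode="fixed"`` reuses the transform of
    ``reference_frame`` for every frame.

    The frame's own hyoid position serves as the anterior hint; the hyoid is
    always anterior to the vertebral column on a lateral view.  Not rebased.
    """
    scale = compute_scale_factor(cal)
    n = len(series)
    conv = series.y_axis_convention
    pos = np.empty((n, 2), dtype=float)
    if mode == "fixed":
        if not 0 <= reference_frame < n:
            raise IndexError(f"reference_frame {reference_frame} out of range")
        tr = build_frame_transform(
            series.c2_px[reference_frame],
            series.c4_px[reference_frame],
            series.hyoid_px[reference_frame],
            conv,
        )
        pos = tr.apply(_resolve_convention(series.hyoid_px, conv)) * scale
    elif mode == "per-frame":
        for i in range(n):
            try:
                tr = build_frame_transform(
                    series.c2_px[i], series.c4_px[i], series.hyoid_px[i], conv
                )
            except (DegenerateAxisError, AmbiguousOrientationError) as exc:
                raise type(exc)(f"frame {series.frame_index[i]}: {exc}") from exc
            pos[i] = tr.apply(_resolve_convention(series.hyoid_px[i], conv)) * scale
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return AnatomicalTrajectory(
        time=series.time.copy(),
        position_mm=pos,
        rebased=False,
        subject_id=series.subject_id,
    )


def rebase_to_start(traj: AnatomicalTrajectory, start_frame: int) -> AnatomicalTrajectory:
    """Shift the trajectory so ``position[start_frame]`` is exactly (0, 0).

    Idempotent: rebasing an already-rebased trajectory at the same frame is a
    no-op.
    """
    if not 0 <= start_frame < len(traj):
        raise IndexError(f"start_frame {start_frame} out of range [0, {len(traj)})")
    shifted = traj.position_mm - traj.position_mm[start_frame]
    return replace(
        traj, position_mm=shifted, rebased=True, start_frame=int(start_frame)
    )
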