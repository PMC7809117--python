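"""End-to-end analysis: landmarks → kinematic profiles → FLR and cohort tables.

``extract_profile`` runs the per-subject chain (anatomical normalization,
swallow-window detection, rebasing, temporal normalization, velocity,
direction angle, discrete summaries).  ``analyze_cohort`` smooths each
kinematic signal with a cohort-wide GCV-selected penalized B-spline basis
and fits the two-group functional regression per signal; Table-style group
summaries come from the raw (unsmoothed) profiles via
:func:`hyoidkin.cohort_stats.summarize_cohort`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import cohort_stats, fda, flr, kinematics
from .geometry import (
    AnatomicalTrajectory,
    LandmarkFrameSeries,
    ScaleCalibration,
    rebase_to_start,
    to_anatomical,
)
from .kinematics import KinematicProfile, SummaryParameters

__all__ = [
    "SIGNALS",
    "SmoothingChoice",
    "CohortAnalysis",
    "extract_profile",
    "extract_cohort",
    "signal_matrix",
    "analyze_cohort",
    "summaries_frame",
]

#: kinematic signals carried through smoothing and functional regression
SIGNALS = ("disp_x", "disp_y", "vel_x", "vel_y", "angle")


def extract_profile(
    series: LandmarkFrameSeries,
    cal: ScaleCalibration,
    window: tuple[int, int] | None = None,
    n_grid: int = 101,
    transform_mode: str = "per-frame",
) -> tuple[KinematicProfile, SummaryParameters]:
    """Run the full per-subject kinematic chain on one landmark series."""
    traj = to_anatomical(series, cal, mode=transform_mode)
    start, end = kinematics.detect_swallow_window(traj, manual_window=window)
    traj = rebase_to_start(traj, start)
    profile = kinematics.normalize_time(traj, (start, end), n_grid=n_grid)
    kinematics.compute_velocity(profile)
    kinematics.compute_direction_angles(profile)
    return profile, kinematics.summarize(profile)


def extract_cohort(
    series_list: Sequence[LandmarkFrameSeries],
    cal: ScaleCalibration | Sequence[ScaleCalibration],
    windows: Sequence[tuple[int, int] | None] | None = None,
    n_grid: int = 101,
    fallback_windows: Sequence[tuple[int, int] | None] | None = None,
) -> tuple[list[KinematicProfile], pd.DataFrame]:
    """Extract profiles and a summary-parameter table for a whole cohort.

    ``windows`` supplies manual swallow windows (None = detect).  When
    automatic detection fails for a subject — the error that in practice
    requests manual annotation — the corresponding ``fallback_windows``
    entry is used as that annotation, if provided.
    """
    cals = (
        list(cal) if isinstance(cal, (list, tuple)) else [cal] * len(series_list)
    )
    if windows is None:
        windows = [None] * len(series_list)
    if fallback_windows is None:
        fallback_windows = [None] * len(series_list)
    profiles: list[KinematicProfile] = []
    rows = []
    for series, c, w, fb in zip(series_list, cals, windows, fallback_windows):
        try:
            profile, summary = extract_profile(series, c, window=w, n_grid=n_grid)
        except kinematics.SwallowDetectionError:
            if fb is None:
                raise
            profile, summary = extract_profile(series, c, window=fb, n_grid=n_grid)
        profiles.append(profile)
        rows.append(asdict(summary))
    return profiles, pd.DataFrame(rows)


def signal_matrix(profiles: Sequence[KinematicProfile], signal: str) -> np.ndarray:
    """Stack one signal across subjects into an (n_subjects, n_grid) matrix.

    The direction angle is unwrapped into a continuous curve first so the
    0/360 seam cannot masquerade as a huge kinematic difference.
    """
    if signal not in SIGNALS:
        raise ValueError(f"unknown signal {signal!r}; expected one of {SIGNALS}")
    if signal == "angle":
        return np.stack([kinematics.continuous_angle(p) for p in profiles])
    return np.stack([np.asarray(getattr(p, signal), dtype=float) for p in profiles])


@dataclass
class SmoothingChoice:
    """GCV-selected smoothing for one signal across the cohort."""

    signal: str
    n_basis: int
    lam: float
    df: float
    mean_gcv: float


@dataclass
class CohortAnalysis:
    """FLR fits, smoothing diagnostics and the cohort summary table."""

    fits: dict[str, flr.FLRFit]
    smoothing: dict[str, SmoothingChoice]
    smoothed: dict[str, np.ndarray]
    summary_table: pd.DataFrame
    design: flr.DesignMatrix


def analyze_cohort(
    profiles: Sequence[KinematicProfile],
    labels: Sequence[str],
    summaries: pd.DataFrame | None = None,
    signals: Iterable[str] = SIGNALS,
    k_grid: Iterable[int] = fda.DEFAULT_K_GRID,
    lambda_grid: Iterable[float] = fda.DEFAULT_LAMBDA_GRID,
    crit: str | float = "normal",
    test_method: str = "auto",
) -> CohortAnalysis:
    """Smooth every signal cohort-wide and fit the two-group FLR per signal.

    One (K, λ) pair is selected per signal by minimizing the mean GCV over
    the cohort's curves, mirroring a single functional model per signal.
    ``summaries`` (one row per subject) feeds the discrete group table; pass
    the frame from :func:`extract_cohort` or leave None to skip it.
    """
    labels = list(labels)
    if len(labels) != len(profiles):
        raise ValueError("labels must match profiles one-to-one")
    design = flr.build_design(labels)
    grid = profiles[0].grid
    fits: dict[str, flr.FLRFit] = {}
    choices: dict[str, SmoothingChoice] = {}
    smoothed: dict[str, np.ndarray] = {}
    for signal in signals:
        Y = signal_matrix(profiles, signal)
        k, lam, sm = fda.select_smoothing(
            Y, k_grid=k_grid, lambda_grid=lambda_grid, t=grid
        )
        choices[signal] = SmoothingChoice(
            signal=signal,
            n_basis=k,
            lam=lam,
            df=sm.df,
            mean_gcv=float(np.mean(sm.gcv())),
        )
        smoothed[signal] = sm.fitted
        fits[signal] = flr.fit_pointwise_flr(sm.fitted, design, grid=grid, crit=crit)
    if summaries is not None:
        table = cohort_stats.summarize_cohort(
            summaries, labels, method=test_method, reference=design.reference
        )
    else:
        table = pd.DataFrame()
    return CohortAnalysis(
        fits=fits,
        smoothing=choices,
        smoothed=smoothed,
        summary_table=table,
        design=design,
    )


def summaries_frame(summaries: Sequence[SummaryParameters]) -> pd.DataFrame:
    """One row per subject from a list of summary-parameter records."""
    return pd.DataFrame([asdict(s) for s in summaries])
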