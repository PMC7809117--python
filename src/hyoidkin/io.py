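"""File round-tripping: landmark CSVs, manifests, kinematics and FLR output.

Landmark files are plain CSVs with header columns
``frame,t_sec,hx,hy,c2x,c2y,c4x,c4y`` (pixel coordinates), one file per
swallow.  A cohort is described by a manifest CSV with columns
``subject_id,landmark_file,group,coin_px,fps``; calibration and the pixel
y-axis convention travel in the manifest / config rather than in the data
files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .flr import FLRFit
from .geometry import LandmarkFrameSeries, ScaleCalibration
from .kinematics import KinematicProfile

__all__ = [
    "LANDMARK_COLUMNS",
    "MANIFEST_COLUMNS",
    "read_landmarks",
    "write_landmarks",
    "read_manifest",
    "write_manifest",
    "write_profile",
    "read_profile",
    "write_flr",
    "write_config",
    "read_config",
]

LANDMARK_COLUMNS = ["frame", "t_sec", "hx", "hy", "c2x", "c2y", "c4x", "c4y"]
MANIFEST_COLUMNS = ["subject_id", "landmark_file", "group", "coin_px", "fps"]


def read_landmarks(
    path: str | Path,
    y_axis_convention: str = "image-down",
    subject_id: str | None = None,
) -> LandmarkFrameSeries:
    """Read one landmark CSV into a :class:`LandmarkFrameSeries`."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing landmark columns {missing}")
    return LandmarkFrameSeries(
        frame_index=df["frame"].to_numpy(),
        time=df["t_sec"].to_numpy(),
        hyoid_px=df[["hx", "hy"]].to_numpy(),
        c2_px=df[["c2x", "c2y"]].to_numpy(),
        c4_px=df[["c4x", "c4y"]].to_numpy(),
        y_axis_convention=y_axis_convention,  # type: ignore[arg-type]
        subject_id=subject_id or path.stem,
    )


def write_landmarks(series: LandmarkFrameSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "frame": series.frame_index,
            "t_sec": series.time,
            "hx": series.hyoid_px[:, 0],
            "hy": series.hyoid_px[:, 1],
            "c2x": series.c2_px[:, 0],
            "c2y": series.c2_px[:, 1],
            "c4x": series.c4_px[:, 0],
            "c4y": series.c4_px[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest; landmark paths resolve relative to it."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing manifest columns {missing}")
    df["landmark_file"] = [
        str((path.parent / p)) if not Path(p).is_absolute() else str(p)
        for p in df["landmark_file"]
    ]
    return df


def write_manifest(rows: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    df = pd.DataFrame(rows)
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


def write_profile(profile: KinematicProfile, path: str | Path) -> None:
    """Write one subject's gridded kinematics as CSV."""
    df = pd.DataFrame(
        {
            "grid": profile.grid,
            "disp_x": profile.disp_x,
            "disp_y": profile.disp_y,
            "vel_x": profile.vel_x,
            "vel_y": profile.vel_y,
            "angle": profile.angle,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# duration_s={profile.duration_s:.6f}\n")
        fh.write(f"# subject_id={profile.subject_id}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_profile(path: str | Path) -> KinematicProfile:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    profile = KinematicProfile(
        grid=df["grid"].to_numpy(),
        disp_x=df["disp_x"].to_numpy(),
        disp_y=df["disp_y"].to_numpy(),
        duration_s=float(meta.get("duration_s", "nan")),
        vel_x=df["vel_x"].to_numpy(),
        vel_y=df["vel_y"].to_numpy(),
        angle=df["angle"].to_numpy(),
        subject_id=meta.get("subject_id", path.stem),
    )
    profile.angle_defined = ~np.isnan(profile.angle)
    return profile


def write_flr(fit: FLRFit, path: str | Path) -> None:
    """FLR output CSV: grid, coefficients, band and significance flags."""
    df = pd.DataFrame(
        {
            "grid": fit.grid,
            "beta_ref": fit.beta_ref,
            "beta_diff": fit.beta_diff,
            "se": fit.se_diff,
            "lo95": fit.lower,
            "hi95": fit.upper,
            "significant": fit.significant.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def write_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
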