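"""Diagnostic figures: mean trajectories and coefficient-function bands."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .flr import FLRFit
from .kinematics import KinematicProfile

__all__ = ["plot_mean_trajectories", "plot_coefficient_function"]


def plot_mean_trajectories(
    profiles: Sequence[KinematicProfile],
    labels: Sequence[str],
    path: str | Path,
) -> None:
    """Group-mean 2-D hyoid trajectories (anterior right, superior up)."""
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 5))
    for group in sorted(set(labels.tolist())):
        sel = [p for p, l in zip(profiles, labels) if l == group]
        mx = np.mean([p.disp_x for p in sel], axis=0)
        my = np.mean([p.disp_y for p in sel], axis=0)
        ax.plot(mx, my, label=f"{group} (n={len(sel)})")
    ax.set_xlabel("horizontal displacement (mm, anterior +)")
    ax.set_ylabel("vertical displacement (mm, superior +)")
    ax.legend()
    ax.set_title("Mean hyoid trajectories")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_coefficient_function(fit: FLRFit, signal: str, path: str | Path) -> None:
    """Group-difference coefficient function with its pointwise 95% band.

    Significant percentile intervals are shaded.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.axhline(0.0, color="k", lw=0.8)
    ax.fill_between(fit.grid, fit.lower, fit.upper, alpha=0.3, label="95% CI")
    ax.plot(fit.grid, fit.beta_diff, lw=1.5, label="beta_diff (poor - good)")
    for lo, hi in fit.intervals:
        ax.axvspan(lo, hi, color="0.85", zorder=0)
    ax.set_xlabel("normalized swallow time (percentile)")
    ax.set_ylabel(f"group difference in {signal}")
    ax.set_title(f"FLR coefficient function: {signal}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
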