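"""Two-group function-on-scalar regression with pointwise confidence bands.

The model is y_i(t) = Z_i1 β_ref(t) + Z_i2 β_diff(t) + ε_i(t), where y_i is
a subject's smoothed kinematic curve and Z codes group membership with
reference coding (the good-prognosis group is the reference, so β_diff(t)
estimates poor − good at each normalized time t).  With a one-way design
the ordinary least squares fit at each grid point reduces to the group
means, and β_diff(t) is exactly the pointwise difference of group mean
curves; the value of the functional framing is the pointwise 95% confidence
band and the significant percentile intervals it yields.

Significance here is pointwise, not family-wise: an interval is reported
wherever the 95% band excludes zero, with no multiplicity correction across
grid points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .fda import FunctionalSample

__all__ = [
    "DesignMatrix",
    "FLRFit",
    "build_design",
    "fit_pointwise_flr",
    "significant_intervals",
]


@dataclass
class DesignMatrix:
    """Reference-coded two-group design.

    Column 0 is the intercept (reference group mean); column 1 indicates the
    non-reference group, so its coefficient is the group difference
    (non-reference minus reference).
    """

    Z: np.ndarray  # (n, 2) with entries in {0, 1}
    labels: np.ndarray  # (n,) original labels
    reference: object
    other: object

    @property
    def n_subjects(self) -> int:
        return self.Z.shape[0]


def build_design(labels: Sequence, reference: object | None = None) -> DesignMatrix:
    """Build the two-group design matrix from per-subject labels.

    ``reference`` names the baseline group; by default the label ``"good"``
    is the reference if present, otherwise the lexicographically first
    label.  Each group must have at least two subjects.
    """
    labels = np.asarray(labels)
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    if reference is None:
        reference = "good" if "good" in levels else levels[0]
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among labels {levels}")
    other = next(l for l in levels if l != reference)
    counts = {l: int(np.sum(labels == l)) for l in levels}
    small = [l for l, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"each group needs >= 2 subjects; too small: {small}")
    Z = np.column_stack(
        [np.ones(len(labels)), (labels == other).astype(float)]
    )
    return DesignMatrix(Z=Z, labels=labels, reference=reference, other=other)


@dataclass
class FLRFit:
    """Pointwise OLS fit of the two-group functional model."""

    grid: np.ndarray
    beta_ref: np.ndarray
    beta_diff: np.ndarray
    se_diff: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    sigma2: np.ndarray  # residual variance function, RSS(t)/(n − p)
    design: DesignMatrix
    crit: float
    significant: np.ndarray  # boolean mask on the grid
    intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if np.any(self.lower > self.beta_diff + 1e-12) or np.any(
            self.upper < self.beta_diff - 1e-12
        ):
            raise ValueError("confidence band must bracket beta_diff")


def _curve_matrix(
    curves: Sequence[FunctionalSample] | np.ndarray, grid: np.ndarray
) -> np.ndarray:
    if isinstance(curves, np.ndarray):
        Y = np.asarray(curves, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != len(grid):
            raise ValueError("curve matrix must be (n_subjects, len(grid))")
        return Y
    basis = curves[0].basis
    if any(c.basis is not basis for c in curves[1:]):
        raise ValueError("all curves must share one basis system")
    B = basis.design_matrix(grid)
    C = np.stack([c.coefficients for c in curves])
    return C @ B.T


def fit_pointwise_flr(
    curves: Sequence[FunctionalSample] | np.ndarray,
    design: DesignMatrix,
    grid: Sequence[float] | None = None,
    conf_level: float = 0.95,
    crit: str | float = "normal",
) -> FLRFit:
    """Fit y_i(t) = Σ_j Z_ij β_j(t) + ε_i(t) by OLS at each grid point.

    ``curves`` is either a list of :class:`FunctionalSample` sharing one
    basis (evaluated on ``grid``) or a ready (n_subjects, n_grid) value
    matrix.  The band is β̂_diff(t) ± crit·SE(t) with SE from the
    homoscedastic pointwise OLS variance σ̂²(t)(ZᵀZ)⁻¹; ``crit`` is the
    normal quantile by default, or Student t(n − p) with ``crit="t"``.
    """
    if grid is None:
        grid = np.linspace(0.0, 100.0, 101)
    grid = np.asarray(grid, dtype=float)
    Y = _curve_matrix(curves, grid)
    Z = design.Z
    n, p = Z.shape
    if Y.shape[0] != n:
        raise ValueError("number of curves must match the design")
    if np.linalg.matrix_rank(Z) < p:
        raise ValueError("design matrix is rank deficient")

    ZtZ_inv = np.linalg.inv(Z.T @ Z)
    beta = ZtZ_inv @ Z.T @ Y  # (p, n_grid)
    resid = Y - Z @ beta
    sigma2 = np.sum(resid**2, axis=0) / (n - p)
    se_diff = np.sqrt(sigma2 * ZtZ_inv[1, 1])

    alpha = 1.0 - conf_level
    if crit == "normal":
        c = float(stats.norm.ppf(1.0 - alpha / 2.0))
    elif crit == "t":
        c = float(stats.t.ppf(1.0 - alpha / 2.0, df=n - p))
    else:
        c = float(crit)

    beta_ref = beta[0]
    beta_diff = beta[1]
    lower = beta_diff - c * se_diff
    upper = beta_diff + c * se_diff
    significant = (lower > 0.0) | (upper < 0.0)
    fit = FLRFit(
        grid=grid,
        beta_ref=beta_ref,
        beta_diff=beta_diff,
        se_diff=se_diff,
        lower=lower,
        upper=upper,
        sigma2=sigma2,
        design=design,
        crit=c,
        significant=significant,
        intervals=[],
    )
    fit.intervals = significant_intervals(fit)
    return fit


def significant_intervals(fit: FLRFit) -> list[tuple[float, float]]:
    """Maximal runs of grid points where the 95% band excludes zero.

    Returned as closed percentile ranges [lo, hi]; a single significant grid
    point yields a degenerate interval lo == hi (short runs are reported —
    there is no minimum-length filter).
    """
    sig = np.asarray(fit.significant, dtype=bool)
    intervals: list[tuple[float, float]] = []
    i = 0
    m = len(sig)
    while i < m:
        if sig[i]:
            j = i
            while j + 1 < m and sig[j + 1]:
                j += 1
            intervals.append((float(fit.grid[i]), float(fit.grid[j])))
            i = j + 1
        else:
            i += 1
    return intervals
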