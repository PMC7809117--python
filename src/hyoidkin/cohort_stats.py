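"""Discrete two-group comparisons for cohort tables.

Continuous kinematic or clinical variables are compared with a pooled
independent-samples t test or the Mann–Whitney U test (normal approximation
with tie correction); ``auto`` picks the t test only when both groups pass
Shapiro–Wilk normality at α = 0.05.  Categorical variables use Pearson's
chi-square (no continuity correction) or Fisher's exact test; ``auto``
switches to Fisher whenever any expected cell count is below 5.  All tests
are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "TestResult",
    "two_sample_compare",
    "categorical_test",
    "summarize_cohort",
    "SUMMARY_PARAMETERS",
]


class TestResult(NamedTuple):
    statistic: float
    pvalue: float
    method: str


@dataclass(frozen=True)
class ContingencyTable:
    """r×c table of nonnegative integer counts with optional labels."""

    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or min(counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", np.round(counts).astype(int))
        if self.counts.sum() == 0:
            raise ValueError("contingency table total must be positive")


def _split_groups(
    values: Sequence[float], labels: Sequence
) -> tuple[np.ndarray, np.ndarray, tuple]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    a = values[labels == levels[0]]
    b = values[labels == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    return a, b, tuple(levels)


def two_sample_compare(
    values: Sequence[float],
    labels: Sequence,
    method: str = "auto",
) -> TestResult:
    """Two-sided comparison of a continuous variable between two groups.

    ``method="t"`` is the pooled-variance independent t test;
    ``"mannwhitney"`` the Mann–Whitney U test with normal approximation and
    tie correction (no continuity correction, so identical samples give
    p = 1 exactly); ``"auto"`` applies Shapiro–Wilk to each group and uses
    the t test only if both are consistent with normality at α = 0.05.
    """
    a, b, _ = _split_groups(values, labels)
    if method == "auto":
        # Shapiro-Wilk needs >= 3 values and nonzero variance
        def normal_ok(x: np.ndarray) -> bool:
            if len(x) < 3 or np.ptp(x) == 0:
                return False
            return stats.shapiro(x).pvalue > 0.05

        method = "t" if (normal_ok(a) and normal_ok(b)) else "mannwhitney"
    if method == "t":
        res = stats.ttest_ind(a, b, equal_var=True)
        return TestResult(float(res.statistic), float(res.pvalue), "t")
    if method == "mannwhitney":
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        return TestResult(float(res.statistic), float(res.pvalue), "mannwhitney")
    raise ValueError(f"unknown method {method!r}")


def categorical_test(
    table: ContingencyTable | np.ndarray | Sequence[Sequence[int]],
    method: str = "auto",
) -> float:
    """Two-sided p-value for association in a contingency table.

    ``"fisher"`` is the exact test (hypergeometric two-sided rule for 2×2:
    sum of all table probabilities no larger than the observed one);
    ``"chi2"`` is Pearson's chi-square without continuity correction;
    ``"auto"`` uses Fisher when any expected count is below 5.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.counts
    if method == "auto":
        expected = stats.contingency.expected_freq(counts)
        method = "fisher" if np.any(expected < 5) else "chi2"
    if method == "fisher":
        res = stats.fisher_exact(counts, alternative="two-sided")
        return float(res.pvalue)
    if method == "chi2":
        res = stats.chi2_contingency(counts, correction=False)
        return float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


#: summary-parameter columns reported in the cohort table, with print labels
SUMMARY_PARAMETERS = {
    "duration_s": "Total swallowing duration (s)",
    "max_backward_x": "Maximal horizontal displacement, backward (mm)",
    "max_forward_x": "Maximal horizontal displacement, forward (mm)",
    "max_upward_y": "Maximal vertical displacement, upward (mm)",
    "time_max_backward_x": "Time to maximal displacement, horizontal backward (percentile)",
    "time_max_forward_x": "Time to maximal displacement, horizontal forward (percentile)",
    "time_max_upward_y": "Time to maximal displacement, vertical upward (percentile)",
    "max_backward_vx": "Maximal horizontal velocity, backward (mm/percentile)",
    "max_forward_vx": "Maximal horizontal velocity, forward (mm/percentile)",
    "max_upward_vy": "Maximal vertical velocity, upward (mm/percentile)",
    "time_max_backward_vx": "Time to maximal velocity, horizontal backward (percentile)",
    "time_max_forward_vx": "Time to maximal velocity, horizontal forward (percentile)",
    "time_max_upward_vy": "Time to maximal velocity, vertical upward (percentile)",
    "mean_early_angle": "Mean direction angle for 5th-20th percentile duration (deg)",
}


def summarize_cohort(
    params: pd.DataFrame,
    labels: Sequence,
    method: str = "auto",
    reference: object = "good",
) -> pd.DataFrame:
    """Group mean ± SD and a two-sample p-value per summary parameter.

    ``params`` holds one row per subject (columns as in
    :data:`SUMMARY_PARAMETERS`, extra columns ignored); SDs are sample
    (n − 1) standard deviations.  Returns one row per parameter with the
    chosen test recorded.
    """
    labels = np.asarray(labels)
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    if reference in levels:
        levels = [reference] + [l for l in levels if l != reference]
    rows = []
    for col, label in SUMMARY_PARAMETERS.items():
        if col not in params.columns:
            continue
        vals = params[col].to_numpy(dtype=float)
        res = two_sample_compare(vals, labels, method=method)
        g0 = vals[labels == levels[0]]
        g1 = vals[labels == levels[1]]
        rows.append(
            {
                "parameter": col,
                "label": label,
                f"mean_{levels[0]}": float(np.mean(g0)),
                f"sd_{levels[0]}": float(np.std(g0, ddof=1)),
                f"mean_{levels[1]}": float(np.mean(g1)),
                f"sd_{levels[1]}": float(np.std(g1, ddof=1)),
                "statistic": res.statistic,
                "p": res.pvalue,
                "test": res.method,
            }
        )
    return pd.DataFrame(rows)
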