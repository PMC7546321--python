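"""ROI feature extraction, clinical correlation, and demographic tests.

Cluster-mean GFC values (Fisher-z units) are correlated with illness
duration within the patient group only; Bonferroni correction handles
the one-test-per-cluster multiplicity.  Demographic group comparisons
use two-sample t-tests for continuous variables and a Pearson chi-square
(no continuity correction) for the sex distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .inference import ClusterResult

__all__ = [
    "CorrelationResult",
    "cluster_means",
    "pearson_corr",
    "bonferroni",
    "two_sample_ttest",
    "two_sample_ttest_from_stats",
    "chi_square_test",
]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def cluster_means(
    gfc_stack: np.ndarray, clusters: list[ClusterResult], mask_coords: np.ndarray
) -> np.ndarray:
    """subjects x clusters table of mean GFC over cluster member voxels.

    ``gfc_stack`` is subjects x mask-voxels in the fixed linearization;
    ``mask_coords`` is the (n_voxels, 3) voxel-coordinate table of the
    columns (``GrayMatterMask.voxel_coords()``).
    """
    gfc_stack = np.asarray(gfc_stack, dtype=np.float64)
    coord_to_col = {tuple(c): j for j, c in enumerate(map(tuple, mask_coords))}
    out = np.empty((gfc_stack.shape[0], len(clusters)))
    for k, cluster in enumerate(clusters):
        cols = [
            coord_to_col[tuple(v)]
            for v in map(tuple, cluster.member_voxels)
            if tuple(v) in coord_to_col
        ]
        if not cols:
            raise ValueError(
                f"cluster {cluster.cluster_id} has no voxels inside the mask"
            )
        out[:, k] = gfc_stack[:, cols].mean(axis=1)
    return out


def pearson_corr(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Product-moment correlation with the exact t-based two-sided p.

    p is computed from ``t = r sqrt(n-2) / sqrt(1 - r^2)`` against a
    Student t distribution with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return CorrelationResult(r=r, p=0.0, n=n)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(r=r, p=float(p), n=n)


def bonferroni(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p) over m tests."""
    p = np.asarray(p_values, dtype=np.float64)
    return np.minimum(1.0, p.size * p)


def two_sample_ttest(
    x: np.ndarray, y: np.ndarray, variant: str = "student_pooled"
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns (t, df, p).

    ``student_pooled`` (default) assumes equal variances; ``welch``
    does not.
    """
    if variant not in ("student_pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    res = stats.ttest_ind(x, y, equal_var=(variant == "student_pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def two_sample_ttest_from_stats(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "student_pooled",
) -> tuple[float, float, float]:
    """Summary-statistic entry point, equivalent to the raw-sample one."""
    if variant not in ("student_pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2,
        equal_var=(variant == "student_pooled"),
    )
    if variant == "student_pooled":
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def chi_square_test(table_2x2: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Returns (chi2, df, p).  The Yates correction is deliberately off;
    it changes the p-value materially at these sample sizes.
    """
    table = np.asarray(table_2x2, dtype=np.float64)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
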