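"""Voxel-wise group inference on GFC maps.

A two-sample comparison with covariates of no interest is fit as a
per-voxel OLS model ``gfc ~ intercept + group + mean_fd + age`` (group
coded patient = 1, control = 0, so negative t means lower GFC in
patients).  Family-wise error across voxels is controlled with the
permutation distribution of the maximum |t| under the Freedman-Lane
scheme: nuisance effects are regressed out once, the residuals are
permuted across subjects, and the full model is refit per permutation.
Testing is two-sided.  Suprathreshold voxels are grouped into connected
components for descriptive cluster reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GroupStatMap",
    "ClusterResult",
    "build_group_design",
    "fit_voxelwise_glm",
    "permutation_fwe",
    "extract_clusters",
]


@dataclass
class GroupStatMap:
    """Per-voxel t statistics for the group contrast, plus FWE results."""

    t: np.ndarray
    df: int
    design_labels: list[str]
    p_fwe: np.ndarray | None = None
    sig_mask: np.ndarray | None = None
    alpha: float | None = None
    n_perm: int | None = None
    zero_variance: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int)
    )


@dataclass
class ClusterResult:
    """Connected suprathreshold component with peak bookkeeping."""

    cluster_id: int
    member_voxels: np.ndarray  # (size, 3) voxel indices
    size: int
    peak_voxel: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    peak_t: float
    direction: str  # "decrease" (t < 0) or "increase"


def build_group_design(
    group: np.ndarray, mean_fd: np.ndarray, age: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """[intercept, group, mean_fd, age] design; group: patient=1."""
    group = np.asarray(group, dtype=np.float64)
    n = group.shape[0]
    design = np.column_stack(
        [np.ones(n), group, np.asarray(mean_fd, float), np.asarray(age, float)]
    )
    return design, ["intercept", "group", "mean_fd", "age"]


def _glm_t(
    Y: np.ndarray, X: np.ndarray, pinv: np.ndarray, contrast_var: float,
    col: int,
) -> np.ndarray:
    """t statistic for one design column, vectorized over voxels."""
    n, p = X.shape
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * contrast_var)
    # voxels whose residual variance is zero up to rounding get t = 0
    tiny = 1e-10 * (np.abs(Y).max() + 1e-300)
    good = se > tiny
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(good, beta[col] / np.where(good, se, 1.0), 0.0)
    return t


def fit_voxelwise_glm(
    gfc_stack: np.ndarray,
    design: np.ndarray,
    labels: list[str] | None = None,
    contrast: str | int = "group",
) -> GroupStatMap:
    """Per-voxel OLS; returns unadjusted group-contrast t map.

    ``gfc_stack`` is subjects x voxels.  Voxels where the residual
    variance is exactly zero (identical maps) get t = 0 and are flagged.
    """
    Y = np.asarray(gfc_stack, dtype=np.float64)
    X = np.asarray(design, dtype=np.float64)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("design rows must match number of subjects")
    labels = labels or [f"c{i}" for i in range(X.shape[1])]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the columns involved in the dependency
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                bad.append(labels[j])
        raise ValueError(f"collinear design; dependent columns: {bad}")
    col = labels.index(contrast) if isinstance(contrast, str) else int(contrast)
    pinv = np.linalg.pinv(X)
    xtx_inv = np.linalg.inv(X.T @ X)
    t = _glm_t(Y, X, pinv, xtx_inv[col, col], col)
    resid = Y - X @ (pinv @ Y)
    tiny = 1e-10 * (np.abs(Y).max() + 1e-300)
    zero_var = np.flatnonzero((resid**2).sum(axis=0) <= tiny**2)
    return GroupStatMap(
        t=t, df=X.shape[0] - X.shape[1], design_labels=list(labels),
        zero_variance=zero_var,
    )


def permutation_fwe(
    gfc_stack: np.ndarray,
    design: np.ndarray,
    labels: list[str] | None = None,
    contrast: str | int = "group",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> GroupStatMap:
    """Max-|t| permutation FWE correction (Freedman-Lane).

    Adjusted p for voxel v is ``(1 + #{max_perm >= |t_obs(v)|}) /
    (n_perm + 1)``; a voxel is significant iff adjusted p < alpha.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if n_perm < 1.0 / alpha - 1:
        import warnings

        warnings.warn(
            f"n_perm={n_perm} cannot resolve alpha={alpha}", stacklevel=2
        )
    result = fit_voxelwise_glm(gfc_stack, design, labels, contrast)
    labels_used = result.design_labels
    col = (
        labels_used.index(contrast) if isinstance(contrast, str) else int(contrast)
    )
    Y = np.asarray(gfc_stack, dtype=np.float64)
    X = np.asarray(design, dtype=np.float64)
    n = X.shape[0]
    Z = np.delete(X, col, axis=1)  # nuisance-only design
    pinv_z = np.linalg.pinv(Z)
    fitted_z = Z @ (pinv_z @ Y)
    resid_z = Y - fitted_z
    pinv_x = np.linalg.pinv(X)
    xtx_inv = np.linalg.inv(X.T @ X)
    cvar = xtx_inv[col, col]

    rng = np.random.default_rng(seed)
    t_obs = np.abs(result.t)
    max_t = np.empty(n_perm)
    n_vox = Y.shape[1]
    df = n - X.shape[1]
    batch = max(1, min(n_perm, int(5e6 // max(1, n * n_vox))))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        # stack b permuted datasets side by side: one BLAS call per refit
        perms = np.stack([rng.permutation(n) for _ in range(b)])
        Y_star = (
            fitted_z[:, None, :] + resid_z[perms].transpose(1, 0, 2)
        ).reshape(n, b * n_vox)
        beta = pinv_x @ Y_star
        resid = Y_star - X @ beta
        sigma2 = (resid**2).sum(axis=0) / df
        se = np.sqrt(sigma2 * cvar)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_star = np.where(se > 0, beta[col] / np.where(se > 0, se, 1.0), 0.0)
        max_t[done:done + b] = (
            np.abs(t_star).reshape(b, n_vox).max(axis=1)
        )
        done += b
    # one voxel's adjusted p: rank of its |t| within the max-null
    counts = np.searchsorted(np.sort(max_t), t_obs, side="left")
    p_fwe = (1.0 + (n_perm - counts)) / (n_perm + 1.0)
    result.p_fwe = p_fwe
    result.sig_mask = p_fwe < alpha
    result.alpha = alpha
    result.n_perm = n_perm
    return result


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_clusters(
    sig_mask_3d: np.ndarray,
    t_map_3d: np.ndarray,
    affine: np.ndarray,
    connectivity: int = 26,
) -> list[ClusterResult]:
    """Connected components of the significance mask with peak info.

    Clusters are sorted by size descending, ties broken by peak |t|
    descending, then by lexicographic peak voxel index.  An empty mask
    yields an empty list.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    sig = np.asarray(sig_mask_3d, dtype=bool)
    t_map = np.asarray(t_map_3d, dtype=np.float64)
    labelled, n_labels = ndimage.label(sig, structure=_STRUCTURES[connectivity])
    clusters = []
    for lab in range(1, n_labels + 1):
        members = np.argwhere(labelled == lab)
        t_vals = t_map[tuple(members.T)]
        peak_local = int(np.argmax(np.abs(t_vals)))
        peak_voxel = tuple(int(v) for v in members[peak_local])
        peak_t = float(t_vals[peak_local])
        peak_mm = tuple(
            float(v)
            for v in (affine @ np.r_[peak_voxel, 1.0])[:3]
        )
        clusters.append(
            ClusterResult(
                cluster_id=0,
                member_voxels=members,
                size=members.shape[0],
                peak_voxel=peak_voxel,
                peak_mm=peak_mm,
                peak_t=peak_t,
                direction="decrease" if peak_t < 0 else "increase",
            )
        )
    clusters.sort(
        key=lambda c: (-c.size, -abs(c.peak_t), c.peak_voxel)
    )
    for i, c in enumerate(clusters):
        c.cluster_id = i + 1
    return clusters
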