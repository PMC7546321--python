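"""Voxel-wise global-brain functional connectivity (GFC / GBC).

For each gray-matter voxel ``a`` with time series ``Ta``, GFC(a) is the
average correlation of ``Ta`` with every other gray-matter voxel::

    GFC(a) = sum_{b != a} r(Ta, Tb) / (n - 1)

Two conventions coexist in the literature and both are provided:

``mean_r``
    average the raw Pearson correlations (fast O(n*T) path via the
    identity sum_b r(a,b) = z_a . sum_b z_b over standardized columns);
``mean_z``
    Fisher z-transform every pairwise correlation, then average
    (blocked O(n^2 * T) computation, memory-bounded).

The default mode is ``mean_z``.  Self-correlation is excluded from the
average in both modes; including it is available behind a flag for
sensitivity checks.  Zero-variance voxels get GFC = 0 and a QC flag
rather than propagating NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .niio import GrayMatterMask, TimeSeriesMatrix, map_to_volume

ATANH_EPS = 1e-7  # clip radius before atanh; caps |z| at ~8.1

__all__ = [
    "GFCMap",
    "standardize",
    "fisher_z",
    "gfc_bruteforce",
    "gfc_fast",
    "subject_gfc_map",
]


@dataclass
class GFCMap:
    """Per-voxel GFC values in the column order of the source matrix."""

    values: np.ndarray
    mode: str
    n_voxels: int
    n_frames: int
    degenerate: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int)
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError("GFC map contains non-finite values")


def standardize(ts: TimeSeriesMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demean and scale each column to unit Euclidean norm.

    Returns ``(z, degenerate)`` where ``degenerate`` flags zero-variance
    columns, which are set to all-zero (their correlation with anything
    is treated as 0 downstream).  For non-degenerate columns the inner
    product ``z_a . z_b`` is exactly the Pearson correlation.
    """
    values = ts.values if isinstance(ts, TimeSeriesMatrix) else np.asarray(ts, float)
    centered = values - values.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    degenerate = norms <= 1e-12 * max(1.0, float(np.abs(values).max(initial=0.0)))
    safe = np.where(degenerate, 1.0, norms)
    z = centered / safe
    z[:, degenerate] = 0.0
    return z, degenerate


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing Fisher transform z = atanh(r), clipped.

    Correlations are clipped to ``[-1 + 1e-7, 1 - 1e-7]`` first so that
    duplicated columns (r = 1) give a large finite value instead of inf.
    """
    return np.arctanh(np.clip(r, -1.0 + ATANH_EPS, 1.0 - ATANH_EPS))


def _check_input(values: np.ndarray) -> None:
    if values.shape[0] < 3:
        raise ValueError("need at least 3 frames")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 voxels")


def gfc_bruteforce(
    ts: TimeSeriesMatrix | np.ndarray,
    mode: str = "mean_z",
    include_self: bool = False,
) -> GFCMap:
    """Reference implementation: explicit double loop over voxel pairs.

    Quadratic in voxels and deliberately naive; used as the oracle for
    :func:`gfc_fast` in tests.
    """
    values = ts.values if isinstance(ts, TimeSeriesMatrix) else np.asarray(ts, float)
    _check_input(values)
    if mode not in ("mean_r", "mean_z"):
        raise ValueError(f"unknown mode {mode!r}")
    t, n = values.shape
    z, degenerate = standardize(values)
    out = np.zeros(n)
    denom = n if include_self else n - 1
    for a in range(n):
        if degenerate[a]:
            continue
        total = 0.0
        for b in range(n):
            if b == a and not include_self:
                continue
            r = 1.0 if b == a else float(z[:, a] @ z[:, b])
            total += fisher_z(r) if mode == "mean_z" else r
        out[a] = total / denom
    return GFCMap(values=out, mode=mode, n_voxels=n, n_frames=t,
                  degenerate=np.flatnonzero(degenerate))


def gfc_fast(
    ts: TimeSeriesMatrix | np.ndarray,
    mode: str = "mean_z",
    include_self: bool = False,
    block_size: int = 512,
) -> GFCMap:
    """Production GFC path; numerically identical to the brute force.

    ``mean_r`` uses the linear identity and runs in O(n*T); ``mean_z``
    computes the pairwise correlation matrix in blocks of ``block_size``
    rows so peak memory stays at ``block_size * n`` floats.
    """
    values = ts.values if isinstance(ts, TimeSeriesMatrix) else np.asarray(ts, float)
    _check_input(values)
    if mode not in ("mean_r", "mean_z"):
        raise ValueError(f"unknown mode {mode!r}")
    if block_size < 1:
        raise ValueError("block_size must be positive")
    t, n = values.shape
    z, degenerate = standardize(values)
    denom = n if include_self else n - 1
    out = np.zeros(n)
    if mode == "mean_r":
        s = z.sum(axis=1)
        r_sum = z.T @ s  # includes the self term r(a,a) = 1
        if include_self:
            out = r_sum / denom
        else:
            out = (r_sum - 1.0) / denom
    else:
        for start in range(0, n, block_size):
            stop = min(start + block_size, n)
            r_block = z[:, start:stop].T @ z  # (block, n)
            zb = fisher_z(r_block)
            rows = np.arange(start, stop)
            if include_self:
                # exact self term: atanh of clipped r(a,a) = 1
                zb[np.arange(stop - start), rows] = fisher_z(1.0)
            else:
                zb[np.arange(stop - start), rows] = 0.0
            out[rows] = zb.sum(axis=1) / denom
    out[degenerate] = 0.0
    return GFCMap(values=out, mode=mode, n_voxels=n, n_frames=t,
                  degenerate=np.flatnonzero(degenerate))


def subject_gfc_map(
    ts: TimeSeriesMatrix,
    mask: GrayMatterMask,
    mode: str = "mean_z",
    include_self: bool = False,
    block_size: int = 512,
) -> tuple[GFCMap, np.ndarray]:
    """Compute a subject's GFC map and place it back on the 3D grid.

    Returns ``(gfc_map, volume3d)``; the volume has 0 outside the mask.
    """
    if ts.n_voxels != mask.n_voxels:
        raise ValueError("matrix columns do not match mask voxel count")
    gmap = gfc_fast(ts, mode=mode, include_self=include_self,
                    block_size=block_size)
    vol = map_to_volume(gmap.values, mask)
    return gmap, vol
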