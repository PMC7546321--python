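"""NIfTI I/O, gray-matter masking, and the 4D-image <-> matrix conversion.

All volumes in one analysis must share a single grid and affine; nothing
here resamples.  The frames x voxels matrix uses a fixed linearization of
the mask (x varies fastest, then y, then z) so that column order is stable
across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume4D",
    "GrayMatterProbabilityMap",
    "GrayMatterMask",
    "TimeSeriesMatrix",
    "read_volume4d",
    "write_volume4d",
    "read_prob_map",
    "write_volume3d",
    "build_gm_mask",
    "to_matrix",
    "map_to_volume",
]


@dataclass
class Volume4D:
    """A 4D BOLD image: ``data[x, y, z, t]`` with affine and TR (seconds)."""

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 frames")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite voxel values")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if not self.tr > 0:
            raise ValueError("tr must be positive")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class GrayMatterProbabilityMap:
    """3D tissue-probability volume with values in [0, 1]."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GrayMatterMask:
    """Boolean inclusion mask; ``n_voxels`` is the n of the GFC formula."""

    data: np.ndarray
    affine: np.ndarray
    n_voxels: int = field(init=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        self.n_voxels = int(self.data.sum())

    def flat_indices(self) -> np.ndarray:
        """Linear indices of mask voxels in the fixed (x-fastest) order."""
        return np.flatnonzero(self.data.ravel(order="F"))

    def voxel_coords(self) -> np.ndarray:
        """(n_voxels, 3) integer voxel coordinates, same order as columns."""
        idx = self.flat_indices()
        return np.column_stack(np.unravel_index(idx, self.data.shape, order="F"))


@dataclass
class TimeSeriesMatrix:
    """frames x n_voxels matrix plus the voxel order it was built with.

    ``scrubbed_frames`` records indices (relative to the matrix the scrub
    was applied to) of frames removed by motion scrubbing.
    """

    values: np.ndarray
    voxel_index: np.ndarray  # (n_voxels, 3) voxel coordinates per column
    tr: float
    scrubbed_frames: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int)
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be frames x voxels")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


def read_volume4d(path: str | Path, tr: float | None = None) -> Volume4D:
    """Load a 4D NIfTI-1 image.

    TR is taken from the header (pixdim[4]) when positive; otherwise it
    must be supplied explicitly.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, file is {data.ndim}D")
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: contains non-finite voxels")
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if header_tr > 0:
        tr_used = header_tr
    elif tr is not None and tr > 0:
        tr_used = float(tr)
    else:
        raise ValueError(f"{path}: header has no TR; pass tr= explicitly")
    return Volume4D(data=data, affine=img.affine, tr=tr_used)


def write_volume4d(vol: Volume4D, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = vol.tr
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_prob_map(path: str | Path) -> GrayMatterProbabilityMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, file is {data.ndim}D")
    return GrayMatterProbabilityMap(data=data, affine=img.affine)


def write_volume3d(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a 3D volume; boolean arrays are stored as uint8."""
    if data.dtype == bool:
        out = data.astype(np.uint8)
    else:
        out = data.astype(np.float32)
    nib.save(nib.Nifti1Image(out, np.asarray(affine, dtype=np.float64)), str(path))


def build_gm_mask(
    prob_map: GrayMatterProbabilityMap, threshold: float = 0.2
) -> GrayMatterMask:
    """Threshold a gray-matter probability map into an analysis mask.

    A voxel is included iff its probability is *strictly* greater than
    ``threshold`` (default 0.2).  The strict inequality matters: with
    probabilities exactly at the threshold, ``>`` and ``>=`` give
    different mask sizes.
    """
    if not (0 <= threshold < 1):
        raise ValueError("threshold must lie in [0, 1)")
    mask = GrayMatterMask(data=prob_map.data > threshold, affine=prob_map.affine)
    if mask.n_voxels < 2:
        raise ValueError(
            f"empty mask: only {mask.n_voxels} voxel(s) exceed {threshold}"
        )
    return mask


def _check_same_grid(shape_a, affine_a, shape_b, affine_b) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise ValueError(f"grid mismatch: {tuple(shape_a)} vs {tuple(shape_b)}")
    if not np.allclose(affine_a, affine_b, atol=1e-6):
        raise ValueError("affine mismatch between volume and mask")


def to_matrix(vol: Volume4D, mask: GrayMatterMask) -> TimeSeriesMatrix:
    """Extract the frames x mask-voxels matrix in the fixed column order."""
    _check_same_grid(vol.shape3d, vol.affine, mask.data.shape, mask.affine)
    idx = mask.flat_indices()
    flat = vol.data.reshape(-1, vol.n_frames, order="F")
    return TimeSeriesMatrix(
        values=flat[idx].T.copy(), voxel_index=mask.voxel_coords(), tr=vol.tr
    )


def map_to_volume(
    values_per_voxel: np.ndarray,
    mask: GrayMatterMask,
    fill: float = 0.0,
) -> np.ndarray:
    """Place one value per mask voxel back into a 3D volume.

    Out-of-mask voxels are written as ``fill`` (use ``np.nan`` to make
    background explicit in viewers).
    """
    values_per_voxel = np.asarray(values_per_voxel, dtype=np.float64)
    if values_per_voxel.shape != (mask.n_voxels,):
        raise ValueError(
            f"expected {mask.n_voxels} values, got {values_per_voxel.shape}"
        )
    flat = np.full(int(np.prod(mask.data.shape)), fill, dtype=np.float64)
    flat[mask.flat_indices()] = values_per_voxel
    return flat.reshape(mask.data.shape, order="F")
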