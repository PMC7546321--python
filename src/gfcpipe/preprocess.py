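"""Resting-state time-series cleaning chain.

Stage order is fixed: drop initial volumes -> motion QC -> spatial
smoothing -> linear detrend -> band-pass filter -> nuisance regression
(Friston-24 motion expansion + white-matter and CSF mean signals; the
global signal is retained) -> framewise-displacement scrubbing.

Scrubbing runs last so that deleted frames cannot leak back in through
the temporal filter; filtering a non-contiguous series is ill-defined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import ndimage

from .niio import GrayMatterMask, TimeSeriesMatrix, Volume4D, to_matrix

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM * this

__all__ = [
    "MotionParams",
    "FDTrace",
    "drop_initial_volumes",
    "qc_motion_exclude",
    "gaussian_smooth",
    "linear_detrend",
    "bandpass_filter",
    "friston24",
    "compute_fd",
    "build_nuisance_design",
    "nuisance_regress",
    "scrub",
    "preprocess_subject",
]


@dataclass
class MotionParams:
    """frames x 6 rigid-body parameters: translations (mm), rotations (rad)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[1] != 6:
            raise ValueError("motion parameters must have 6 columns")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_file(cls, path, rotation_unit: str = "radians") -> "MotionParams":
        values = np.loadtxt(path, ndmin=2)
        if rotation_unit == "degrees":
            values = values.copy()
            values[:, 3:] = np.deg2rad(values[:, 3:])
        elif rotation_unit != "radians":
            raise ValueError(f"unknown rotation unit {rotation_unit!r}")
        return cls(values=values)


@dataclass
class FDTrace:
    """Per-frame framewise displacement (mm), Power's formulation."""

    fd: np.ndarray
    threshold: float
    flagged: np.ndarray = field(init=False)
    mean_fd: float = field(init=False)

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=np.float64)
        if (self.fd < 0).any():
            raise ValueError("FD cannot be negative")
        self.flagged = np.flatnonzero(self.fd > self.threshold)
        self.mean_fd = float(self.fd.mean())


def drop_initial_volumes(
    vol: Volume4D, motion: MotionParams, k: int = 10
) -> tuple[Volume4D, MotionParams]:
    """Remove the first ``k`` frames from image and motion in lockstep.

    The first frames of an EPI run are acquired before the longitudinal
    magnetization reaches steady state and are conventionally discarded.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= vol.n_frames:
        raise ValueError(f"cannot drop {k} of {vol.n_frames} frames")
    if motion.n_frames != vol.n_frames:
        raise ValueError("motion frame count does not match image")
    if k == 0:
        return vol, motion
    return (
        Volume4D(data=vol.data[..., k:], affine=vol.affine, tr=vol.tr),
        MotionParams(values=motion.values[k:]),
    )


def qc_motion_exclude(
    motion: MotionParams,
    max_trans_mm: float = 2.0,
    max_rot_deg: float = 2.0,
) -> tuple[bool, int | None]:
    """Per-axis excessive-motion check against the reference frame.

    Returns ``(passed, first_offending_frame)``.  A subject fails if any
    frame's |translation| exceeds ``max_trans_mm`` on any axis or any
    |rotation| exceeds ``max_rot_deg`` on any axis (parameters are in
    radians internally).
    """
    max_rot_rad = np.deg2rad(max_rot_deg)
    bad = (np.abs(motion.values[:, :3]) > max_trans_mm).any(axis=1) | (
        np.abs(motion.values[:, 3:]) > max_rot_rad
    ).any(axis=1)
    if bad.any():
        return False, int(np.flatnonzero(bad)[0])
    return True, None


def gaussian_smooth(vol: Volume4D, fwhm_mm: float = 4.0) -> Volume4D:
    """Per-frame isotropic Gaussian smoothing.

    sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` converted to voxel
    units using that axis' voxel size; ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return vol
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vol.voxel_sizes()
    out = vol.data
    for axis in range(3):  # spatial axes only; frames stay independent
        out = ndimage.gaussian_filter1d(
            out, sigma_vox[axis], axis=axis, mode="reflect"
        )
    return Volume4D(data=out, affine=vol.affine, tr=vol.tr)


def _residualize(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    # thin-QR projection; design is assumed full column rank here
    q, _ = np.linalg.qr(design)
    return values - q @ (q.T @ values)


def linear_detrend(ts: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Per-voxel OLS removal of intercept and linear trend."""
    t = np.arange(ts.n_frames, dtype=np.float64)
    design = np.column_stack([np.ones_like(t), t])
    return TimeSeriesMatrix(
        values=_residualize(ts.values, design),
        voxel_index=ts.voxel_index,
        tr=ts.tr,
        scrubbed_frames=ts.scrubbed_frames,
    )


def bandpass_filter(
    ts: TimeSeriesMatrix,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    method: str = "ideal",
    order: int = 4,
) -> TimeSeriesMatrix:
    """Temporal band-pass filter.

    ``method="ideal"`` (default): rectangular frequency-domain filter —
    discrete bins with ``low_hz <= f <= high_hz`` are retained, every
    other bin including DC is zeroed, output is real.
    ``method="butterworth"``: zero-phase (forward-backward) Butterworth
    of the given order, available for sensitivity analysis.
    """
    nyquist = 0.5 / ts.tr
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low < high")
    if high_hz >= nyquist:
        raise ValueError(f"high cut {high_hz} Hz >= Nyquist {nyquist} Hz")
    n = ts.n_frames
    if method == "ideal":
        freqs = np.fft.rfftfreq(n, d=ts.tr)
        keep = (freqs >= low_hz) & (freqs <= high_hz)
        spec = np.fft.rfft(ts.values, axis=0)
        spec[~keep] = 0.0
        values = np.fft.irfft(spec, n=n, axis=0)
    elif method == "butterworth":
        from scipy import signal

        low = max(low_hz, 1e-6)
        sos = signal.butter(order, [low, high_hz], btype="bandpass",
                            fs=1.0 / ts.tr, output="sos")
        values = signal.sosfiltfilt(sos, ts.values, axis=0)
    else:
        raise ValueError(f"unknown band-pass method {method!r}")
    return TimeSeriesMatrix(
        values=values,
        voxel_index=ts.voxel_index,
        tr=ts.tr,
        scrubbed_frames=ts.scrubbed_frames,
    )


def friston24(motion: MotionParams) -> np.ndarray:
    """Friston 24-parameter motion expansion.

    Columns are the 6 parameters p(t), their one-frame lags p(t-1)
    (zero-padded at t = 0), and the squares of both, giving 24 columns.
    """
    p = motion.values
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.hstack([p, lag, p**2, lag**2])


def compute_fd(
    motion: MotionParams,
    sphere_radius_mm: float = 50.0,
    threshold: float = 0.2,
) -> FDTrace:
    """Framewise displacement: sum of absolute backward differences.

    Rotational steps (radians) are converted to mm as arc length on a
    sphere of ``sphere_radius_mm`` (50 mm by convention).  FD of the
    first frame is 0.
    """
    d = np.abs(np.diff(motion.values, axis=0))
    fd = np.concatenate(
        [[0.0], d[:, :3].sum(axis=1) + sphere_radius_mm * d[:, 3:].sum(axis=1)]
    )
    return FDTrace(fd=fd, threshold=threshold)


def build_nuisance_design(
    motion: MotionParams, wm_signal: np.ndarray, csf_signal: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Intercept + Friston-24 + WM mean + CSF mean: 27 labelled columns."""
    f24 = friston24(motion)
    n = f24.shape[0]
    wm = np.asarray(wm_signal, dtype=np.float64).reshape(n)
    csf = np.asarray(csf_signal, dtype=np.float64).reshape(n)
    design = np.column_stack([np.ones(n), f24, wm, csf])
    labels = (
        ["intercept"]
        + [f"mot{i}" for i in range(6)]
        + [f"mot{i}_lag" for i in range(6)]
        + [f"mot{i}_sq" for i in range(6)]
        + [f"mot{i}_lag_sq" for i in range(6)]
        + ["wm", "csf"]
    )
    return design, labels


def nuisance_regress(
    ts: TimeSeriesMatrix,
    design: np.ndarray,
    labels: list[str] | None = None,
) -> TimeSeriesMatrix:
    """Per-voxel OLS residualization against the nuisance design.

    Rank-deficient designs are handled by dropping linearly dependent
    columns (QR with column pivoting) with a warning naming them.
    """
    design = np.asarray(design, dtype=np.float64)
    if design.shape[0] != ts.n_frames:
        raise ValueError("design rows must match frame count")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        _, _, piv = sla.qr(design, pivoting=True, mode="economic")
        keep = np.sort(piv[:rank])
        dropped = sorted(set(range(design.shape[1])) - set(keep))
        names = (
            [labels[j] for j in dropped] if labels is not None else list(dropped)
        )
        msg = f"nuisance design rank-deficient; dropping columns {names}"
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)
        design = design[:, keep]
    return TimeSeriesMatrix(
        values=_residualize(ts.values, design),
        voxel_index=ts.voxel_index,
        tr=ts.tr,
        scrubbed_frames=ts.scrubbed_frames,
    )


def scrub(
    ts: TimeSeriesMatrix,
    fd_trace: FDTrace,
    threshold_mm: float = 0.2,
    min_frames: int = 30,
) -> TimeSeriesMatrix:
    """Delete frames with FD strictly above ``threshold_mm``.

    Only the offending frame is removed (no backward/forward
    augmentation).  Errors out if fewer than ``min_frames`` remain.
    """
    if fd_trace.fd.shape[0] != ts.n_frames:
        raise ValueError("FD trace length must match frame count")
    bad = np.flatnonzero(fd_trace.fd > threshold_mm)
    if ts.n_frames - bad.size < min_frames:
        raise ValueError(
            f"scrubbing would leave {ts.n_frames - bad.size} frames "
            f"(< {min_frames})"
        )
    keep = np.setdiff1d(np.arange(ts.n_frames), bad)
    return TimeSeriesMatrix(
        values=ts.values[keep],
        voxel_index=ts.voxel_index,
        tr=ts.tr,
        scrubbed_frames=bad,
    )


def preprocess_subject(
    vol: Volume4D,
    motion: MotionParams,
    gm_mask: GrayMatterMask,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    *,
    k_drop: int = 10,
    fwhm_mm: float = 4.0,
    band: tuple[float, float] = (0.01, 0.08),
    fd_threshold: float = 0.2,
    fd_sphere_radius_mm: float = 50.0,
    max_trans_mm: float = 2.0,
    max_rot_deg: float = 2.0,
    scrub_floor: int = 30,
    erode_wm: bool = True,
) -> tuple[TimeSeriesMatrix | None, dict]:
    """Run the full per-subject chain; returns (matrix, report).

    The matrix is ``None`` when the subject fails motion QC.  WM and CSF
    mean signals are extracted from the smoothed image and passed through
    the same detrend + band-pass stages as the data before entering the
    nuisance design, so the regression removes the in-band part of those
    signals.  The WM mask is eroded by one voxel by default so the mean
    is taken from a white-matter-centered region.
    """
    report: dict = {"k_drop": k_drop, "n_frames_in": vol.n_frames}
    vol, motion = drop_initial_volumes(vol, motion, k_drop)

    ok, offending = qc_motion_exclude(motion, max_trans_mm, max_rot_deg)
    fd_trace = compute_fd(motion, fd_sphere_radius_mm, fd_threshold)
    report.update(qc_passed=bool(ok), qc_offending_frame=offending,
                  mean_fd=fd_trace.mean_fd)
    if not ok:
        report["exclusion_reason"] = "motion QC failed"
        return None, report
    n_left = int((fd_trace.fd <= fd_threshold).sum())
    if n_left < scrub_floor:
        report["exclusion_reason"] = (
            f"scrubbing would leave {n_left} frames (< {scrub_floor})"
        )
        return None, report

    vol = gaussian_smooth(vol, fwhm_mm)

    wm = np.asarray(wm_mask, dtype=bool)
    if erode_wm and ndimage.binary_erosion(wm).any():
        wm = ndimage.binary_erosion(wm)
    csf = np.asarray(csf_mask, dtype=bool)

    def clean(mat: TimeSeriesMatrix) -> TimeSeriesMatrix:
        return bandpass_filter(linear_detrend(mat), *band)

    ts = clean(to_matrix(vol, gm_mask))
    flat = vol.data.reshape(-1, vol.n_frames, order="F")
    nuis = {}
    for name, m in (("wm", wm), ("csf", csf)):
        sig = flat[np.flatnonzero(m.ravel(order="F"))].mean(axis=0)
        tmp = TimeSeriesMatrix(values=sig[:, None], voxel_index=np.zeros((1, 3), int),
                               tr=vol.tr)
        nuis[name] = clean(tmp).values[:, 0]

    design, labels = build_nuisance_design(motion, nuis["wm"], nuis["csf"])
    ts = nuisance_regress(ts, design, labels)
    ts = scrub(ts, fd_trace, fd_threshold, scrub_floor)
    report.update(
        n_scrubbed=int(ts.scrubbed_frames.size),
        scrubbed_frames=[int(i) for i in ts.scrubbed_frames],
        n_frames_retained=ts.n_frames,
    )
    return ts, report
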