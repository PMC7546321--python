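"""Synthetic resting-state cohort generator.

Emulates the data structure of a two-group (patients vs controls)
resting-state study: per-subject 4D BOLD volumes on a common ~3 mm grid,
6-parameter rigid-body motion traces, a gray-matter probability map, and
a cohort table with age, sex, education and (patients only) illness
duration in months.

Generative model per gray-matter voxel v::

    x_v(t) = b_g(v) * g(t) + b_r(v) * s_k(t) + sigma * eps_v(t)

where g is a global latent signal shared by all voxels, s_k is a latent
signal private to effect region k, and eps is white noise.  Latent
signals are sums of sinusoids with random phases at frequencies drawn
inside the analysis band (0.01-0.08 Hz), so the band-pass stage
preserves them by construction.  Patients have the global coupling
b_g reduced inside the designated effect regions; everywhere else the
two groups are statistically identical.  Each subject carries a scalar
coupling deviation z; for patients, illness duration is generated as
``baseline + duration_slope * z + noise``, so duration is positively
coupled to effect-region connectivity by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .niio import (
    GrayMatterProbabilityMap,
    Volume4D,
    write_volume3d,
    write_volume4d,
)
from .preprocess import MotionParams, compute_fd

__all__ = [
    "EffectRegion",
    "CohortSpec",
    "SubjectRecord",
    "SyntheticCohort",
    "default_effect_regions",
    "generate_gm_prob_map",
    "generate_tissue_masks",
    "generate_motion",
    "generate_subject_timeseries",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class EffectRegion:
    """Spherical blob: center in voxel indices, radius in mm."""

    center_vox: tuple[int, int, int]
    radius_mm: float


def default_effect_regions(
    grid_shape: tuple[int, int, int], voxel_size: float
) -> list[EffectRegion]:
    """Two illustrative blobs: a deep thalamus-like one and a smaller
    inferior cerebellum-like one.  No anatomical claim is made; they
    simply mirror a two-cluster ground truth.
    """
    c = (np.asarray(grid_shape) - 1) / 2.0
    scale = min(grid_shape) / 24.0
    thal = tuple(int(round(x)) for x in c + np.array([-4, -2, 1]) * scale)
    cereb = tuple(int(round(x)) for x in c + np.array([3, -4, -5]) * scale)
    return [
        EffectRegion(center_vox=thal, radius_mm=2.5 * scale * voxel_size),
        EffectRegion(center_vox=cereb, radius_mm=2.0 * scale * voxel_size),
    ]


@dataclass
class CohortSpec:
    """All knobs of the synthetic study; defaults emulate the target
    cohort: 20 patients vs 23 controls, 250 volumes at TR = 2 s on a
    3 mm 24^3 grid."""

    n_patients: int = 20
    n_controls: int = 23
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 3.0
    n_volumes: int = 250
    tr: float = 2.0
    global_coupling_control: float = 1.0
    global_coupling_patient_effect: float = 0.4
    regional_coupling: float = 0.4
    coupling_jitter_sd: float = 0.25
    noise_sd: float = 1.0
    effect_regions: list[EffectRegion] | None = None
    duration_baseline: float = 20.75
    duration_slope: float = 15.0
    duration_noise_sd: float = 5.0
    mean_fd_patient: float = 0.31
    mean_fd_control: float = 0.39
    fd_between_sd: float = 0.10
    spike_rate: float = 0.05
    n_latent_components: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        if self.n_volumes <= 0:
            raise ValueError("n_volumes must be positive")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        if not (
            0
            <= self.global_coupling_patient_effect
            <= self.global_coupling_control
        ):
            raise ValueError(
                "patient effect coupling must lie in [0, control coupling]"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.effect_regions is None:
            self.effect_regions = default_effect_regions(
                tuple(self.grid_shape), self.voxel_size
            )

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls


@dataclass
class SubjectRecord:
    id: str
    group: str  # "patient" | "control"
    age: int
    sex: str  # "male" | "female"
    education_years: int
    duration_months: int | None  # patients only
    coupling_z: float  # standardized effect-region coupling deviation
    target_mean_fd: float
    seed: int


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    subjects: list[SubjectRecord]
    gm_prob: GrayMatterProbabilityMap
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    truth: dict = field(default_factory=dict)

    def subject_image(self, record: SubjectRecord) -> Volume4D:
        """Generate (lazily, reproducibly) one subject's 4D image."""
        return generate_subject_timeseries(
            self.spec, record.group, record.seed,
            coupling_z=record.coupling_z, gm_prob=self.gm_prob,
        )

    def subject_motion(self, record: SubjectRecord) -> MotionParams:
        return generate_motion(
            self.spec.n_volumes,
            record.target_mean_fd,
            self.spec.spike_rate,
            seed=record.seed + 1,
        )


def _tissue_spheres(
    grid_shape: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic CSF (central sphere) and WM (offset sphere) regions.

    Positioned away from the default effect regions so that carving them
    out of the gray-matter map leaves a single connected mask and the
    nuisance signals cannot overlap the implanted effects.
    """
    shape = tuple(int(s) for s in grid_shape)
    center = (np.asarray(shape) - 1) / 2.0
    coords = np.indices(shape, dtype=np.float64)
    scale = min(shape) / 24.0
    d_csf = np.sqrt(sum((coords[i] - center[i]) ** 2 for i in range(3)))
    wm_center = center + np.array([4.0, 3.0, 2.0]) * scale
    d_wm = np.sqrt(sum((coords[i] - wm_center[i]) ** 2 for i in range(3)))
    # radius floors keep the pockets non-empty on small grids
    return d_csf <= max(1.5 * scale, 0.9), d_wm <= max(2.5 * scale, 1.3)


def generate_gm_prob_map(
    grid_shape: tuple[int, int, int], voxel_size: float = 3.0
) -> GrayMatterProbabilityMap:
    """Deterministic brain-like probability map: a smooth sigmoid ball
    with low-probability WM and CSF pockets carved out.

    The gray-matter interior has probability >= 0.5, the box boundary is
    ~0, the tissue pockets sit below the 0.2 analysis threshold (as in a
    real tissue-probability segmentation), and thresholding at 0.2
    yields a single connected mask.  The affine centers mm coordinates
    on the middle of the grid.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or any(s < 8 for s in grid_shape):
        raise ValueError(f"degenerate grid shape {grid_shape}: each axis >= 8")
    center = (np.asarray(grid_shape) - 1) / 2.0
    coords = np.indices(grid_shape, dtype=np.float64)
    dist = np.sqrt(sum((coords[i] - center[i]) ** 2 for i in range(3)))
    radius = 0.8 * min(grid_shape) / 2.0
    prob = 1.0 / (1.0 + np.exp((dist - radius) / 0.6))
    csf, wm = _tissue_spheres(grid_shape)
    prob[csf | wm] *= 0.1
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = -center * voxel_size
    return GrayMatterProbabilityMap(data=np.clip(prob, 0.0, 1.0), affine=affine)


def _region_mask(
    grid_shape: tuple[int, int, int], region: EffectRegion, voxel_size: float
) -> np.ndarray:
    coords = np.indices(grid_shape, dtype=np.float64)
    c = np.asarray(region.center_vox, dtype=np.float64)
    dist_mm = voxel_size * np.sqrt(
        sum((coords[i] - c[i]) ** 2 for i in range(3))
    )
    return dist_mm <= region.radius_mm


def generate_tissue_masks(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic WM and CSF masks for nuisance-signal extraction.

    These are the tissue pockets carved out of the gray-matter map; any
    overlap with the configured effect regions is removed so nuisance
    regression cannot touch the implanted signal directly.
    """
    shape = tuple(spec.grid_shape)
    csf, wm = _tissue_spheres(shape)
    effect = np.zeros(shape, dtype=bool)
    for region in spec.effect_regions:
        effect |= _region_mask(shape, region, spec.voxel_size)
    wm &= ~effect
    csf &= ~effect
    if not wm.any() or not csf.any():
        raise ValueError("tissue masks empty; grid too small")
    return wm, csf


def generate_motion(
    n_volumes: int,
    target_mean_fd: float,
    spike_rate: float = 0.05,
    seed: int = 0,
) -> MotionParams:
    """Mean-reverting random-walk motion trace hitting a target mean FD.

    The six parameters follow an AR(1) process; the trace is rescaled so
    the realized mean framewise displacement equals ``target_mean_fd``
    exactly (FD is 1-homogeneous in the parameters).  With
    ``spike_rate > 0`` occasional large steps are injected and at least
    one frame is guaranteed to exceed the 0.2 mm scrubbing threshold.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    if target_mean_fd < 0:
        raise ValueError("target mean FD must be non-negative")
    if target_mean_fd == 0:
        return MotionParams(values=np.zeros((n_volumes, 6)))
    rng = np.random.default_rng(seed)
    rho = 0.8  # mean reversion keeps positions inside the 2 mm / 2 deg QC box
    # split the FD budget evenly between translations and rotations
    s_t = (target_mean_fd / 2.0) / (3.0 * np.sqrt(2.0 / np.pi))
    s_r = (target_mean_fd / 2.0) / (150.0 * np.sqrt(2.0 / np.pi))
    steps = rng.standard_normal((n_volumes, 6)) * np.r_[[s_t] * 3, [s_r] * 3]
    # right-skewed single-frame burst envelope: real FD traces have a low
    # median and occasional movement spikes; truncating the log-normal
    # keeps any one step small enough not to break the QC position limit
    w = np.clip(rng.standard_normal(n_volumes), -2.0, 2.0)
    steps *= np.exp(1.2 * w - 0.72)[:, None]
    if spike_rate > 0:
        spikes = rng.random(n_volumes - 1) < spike_rate
        spikes[rng.integers(1, n_volumes) - 1] = True  # ensure >= 1 spike
        steps[1:][spikes, 0] += rng.choice([-1, 1], spikes.sum()) * (
            3.0 * target_mean_fd
        )
    p = np.zeros((n_volumes, 6))
    for t in range(1, n_volumes):
        p[t] = rho * p[t - 1] + steps[t]
    realized = compute_fd(MotionParams(values=p)).mean_fd
    if realized > 0:
        p *= target_mean_fd / realized
    if spike_rate > 0:
        # rescaling may have shrunk spikes below threshold; re-assert one
        fd = compute_fd(MotionParams(values=p))
        if not (fd.fd > 0.2).any():
            t = int(np.argmax(fd.fd[1:])) + 1
            p[t:, 0] += 0.25  # one extra 0.25 mm step at the worst frame
    return MotionParams(values=p)


def _latent_signal(rng: np.random.Generator, n_volumes: int, tr: float,
                   n_components: int) -> np.ndarray:
    """Unit-variance sum of sinusoids at in-band frequencies.

    Frequencies are drawn in [0.012, 0.078] Hz, safely inside the
    0.01-0.08 Hz analysis band, so essentially all signal power survives
    band-pass filtering.
    """
    t = np.arange(n_volumes) * tr
    freqs = rng.uniform(0.012, 0.078, n_components)
    phases = rng.uniform(0, 2 * np.pi, n_components)
    sig = np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None]).sum(axis=0)
    sd = sig.std()
    return sig / sd if sd > 0 else sig


def _coupling_map(
    spec: CohortSpec, group: str, coupling_z: float
) -> np.ndarray:
    """Per-voxel global coupling b_g for one subject.

    Background gray matter carries the control coupling for everyone.
    Inside the effect regions patients get the reduced mean coupling,
    jittered by the subject's standardized severity ``coupling_z``
    (disease-severity heterogeneity); controls stay at the healthy
    baseline, so outside-region coupling is identical across groups and
    within-region control variance reflects only measurement noise.
    """
    if group not in ("patient", "control"):
        raise ValueError(f"unknown group {group!r}")
    b = np.full(tuple(spec.grid_shape), spec.global_coupling_control)
    if group == "patient":
        effect_value = float(np.clip(
            spec.global_coupling_patient_effect
            + spec.coupling_jitter_sd * coupling_z,
            0.0, spec.global_coupling_control,
        ))
        for region in spec.effect_regions:
            b[_region_mask(tuple(spec.grid_shape), region, spec.voxel_size)] = (
                effect_value
            )
    return b


def generate_subject_timeseries(
    spec: CohortSpec,
    group: str,
    subject_seed: int,
    coupling_z: float = 0.0,
    gm_prob: GrayMatterProbabilityMap | None = None,
) -> Volume4D:
    """One subject's 4D BOLD image under the generative model."""
    if group not in ("patient", "control"):
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(subject_seed)
    if gm_prob is None:
        gm_prob = generate_gm_prob_map(tuple(spec.grid_shape), spec.voxel_size)
    shape = tuple(spec.grid_shape)
    T = spec.n_volumes
    g = _latent_signal(rng, T, spec.tr, spec.n_latent_components)
    # coupling attenuated toward the brain edge so out-of-mask voxels
    # are (almost) pure noise while deep voxels carry full signal
    attenuation = np.minimum(gm_prob.data / 0.5, 1.0)
    b_g = _coupling_map(spec, group, coupling_z) * attenuation
    data = spec.noise_sd * rng.standard_normal(shape + (T,))
    data += b_g[..., None] * g
    for region in spec.effect_regions:
        s_k = _latent_signal(rng, T, spec.tr, spec.n_latent_components)
        m = _region_mask(shape, region, spec.voxel_size) & (gm_prob.data > 0.2)
        data[m] += spec.regional_coupling * s_k
    # WM and CSF pockets carry their own latent signals, independent of
    # the global one, so the nuisance regressors are structured but do
    # not remove the retained global signal from gray matter
    csf, wm = _tissue_spheres(shape)
    for tissue in (csf, wm):
        tissue_sig = _latent_signal(rng, T, spec.tr, spec.n_latent_components)
        data[tissue] += 0.8 * tissue_sig
    return Volume4D(data=data, affine=gm_prob.affine, tr=spec.tr)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw the full cohort: demographics, durations, seeds, truth.

    Images and motion traces are generated on demand from per-subject
    seeds (see :meth:`SyntheticCohort.subject_image`), so the cohort
    object itself stays small.  Identical specs (including seed) yield
    bit-identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    gm_prob = generate_gm_prob_map(tuple(spec.grid_shape), spec.voxel_size)
    wm_mask, csf_mask = generate_tissue_masks(spec)
    subject_seeds = rng.integers(0, 2**31 - 1, size=2 * spec.n_subjects)

    def truncated_age(mean: float, sd: float) -> int:
        while True:
            a = rng.normal(mean, sd)
            if 18 <= a <= 65:
                return int(round(a))

    subjects: list[SubjectRecord] = []
    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    # demographic targets: patients ~N(52.6, 8.7^2), controls ~N(49.7, 6.5^2)
    demo = {
        "patient": dict(age=(52.55, 8.66), edu=(10.20, 3.56), p_male=7 / 20,
                        fd=spec.mean_fd_patient),
        "control": dict(age=(49.69, 6.51), edu=(8.61, 2.27), p_male=4 / 23,
                        fd=spec.mean_fd_control),
    }
    for i, group in enumerate(groups):
        d = demo[group]
        z = float(rng.standard_normal())
        duration = None
        if group == "patient":
            raw = (
                spec.duration_baseline
                + spec.duration_slope * z
                + rng.normal(0, spec.duration_noise_sd)
            )
            duration = max(1, int(round(raw)))
        target_fd = max(0.05, rng.normal(d["fd"], spec.fd_between_sd))
        subjects.append(
            SubjectRecord(
                id=f"sub-{i + 1:03d}",
                group=group,
                age=truncated_age(*d["age"]),
                sex="male" if rng.random() < d["p_male"] else "female",
                education_years=max(0, int(round(rng.normal(*d["edu"])))),
                duration_months=duration,
                coupling_z=z,
                target_mean_fd=float(target_fd),
                seed=int(subject_seeds[2 * i]),
            )
        )

    gm_mask = gm_prob.data > 0.2
    effect_masks = {}
    for k, region in enumerate(spec.effect_regions):
        m = _region_mask(tuple(spec.grid_shape), region, spec.voxel_size)
        effect_masks[f"region_{k}"] = (m & gm_mask)
    truth = {
        "effect_regions": {
            name: [[int(x), int(y), int(z_)] for x, y, z_ in np.argwhere(m)]
            for name, m in effect_masks.items()
        },
        "global_coupling_control": spec.global_coupling_control,
        "global_coupling_patient_effect": spec.global_coupling_patient_effect,
        "subject_coupling_z": {s.id: s.coupling_z for s in subjects},
    }
    return SyntheticCohort(
        spec=spec, subjects=subjects, gm_prob=gm_prob,
        wm_mask=wm_mask, csf_mask=csf_mask, truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Materialize the cohort on disk in the layout the pipeline reads.

    Writes ``sub-XXX_bold.nii.gz``, ``sub-XXX_motion.txt`` (6 columns:
    translations mm, rotations radians), ``gm_prob.nii.gz``,
    ``wm_mask.nii.gz``, ``csf_mask.nii.gz``, ``participants.tsv`` and
    ``truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = cohort.spec
    affine = cohort.gm_prob.affine
    write_volume3d(cohort.gm_prob.data, affine, out / "gm_prob.nii.gz")
    write_volume3d(cohort.wm_mask, affine, out / "wm_mask.nii.gz")
    write_volume3d(cohort.csf_mask, affine, out / "csf_mask.nii.gz")
    rows = ["id\tgroup\tage\tsex\teducation_years\tduration_months"]
    for rec in cohort.subjects:
        vol = cohort.subject_image(rec)
        write_volume4d(vol, out / f"{rec.id}_bold.nii.gz")
        motion = cohort.subject_motion(rec)
        np.savetxt(out / f"{rec.id}_motion.txt", motion.values, fmt="%.8f")
        dur = "" if rec.duration_months is None else str(rec.duration_months)
        rows.append(
            f"{rec.id}\t{rec.group}\t{rec.age}\t{rec.sex}"
            f"\t{rec.education_years}\t{dur}"
        )
    (out / "participants.tsv").write_text("\n".join(rows) + "\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    with open(out / "cohort_spec.json", "w") as fh:
        spec_dict = asdict(spec)
        spec_dict["effect_regions"] = [
            {"center_vox": list(r.center_vox), "radius_mm": r.radius_mm}
            for r in spec.effect_regions
        ]
        json.dump(spec_dict, fh, indent=1)
    return out
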