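"""End-to-end orchestration: simulate -> preprocess -> GFC -> group
inference -> clinical correlation -> classification -> report.

Two entry layers:

* :func:`analyze_cohort` runs the full analysis on an in-memory
  :class:`~gfcpipe.simulate.SyntheticCohort` (or any equivalent data
  provider) and returns a :class:`PipelineResult`;
* :func:`run_pipeline` is the disk-based variant behind the CLI: it
  materializes/reads the cohort layout, calls the same core, and writes
  every stage artifact plus a provenance record into a run directory.

Subjects failing motion QC are excluded with a logged reason; all
reported subject counts reflect exclusions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassificationReport, ROCReport, loocv_svm, roc_curve
from .clinical import (
    bonferroni,
    chi_square_test,
    cluster_means,
    pearson_corr,
    two_sample_ttest,
)
from .config import PipelineConfig
from .gfc import gfc_fast
from .inference import (
    ClusterResult,
    build_group_design,
    extract_clusters,
    permutation_fwe,
)
from .niio import (
    GrayMatterMask,
    Volume4D,
    build_gm_mask,
    map_to_volume,
    read_prob_map,
    read_volume4d,
    write_volume3d,
    write_volume4d,
)
from .preprocess import MotionParams, preprocess_subject
from .simulate import CohortSpec, SyntheticCohort, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "analyze_cohort", "run_pipeline", "make_report"]


@dataclass
class PipelineResult:
    included: list  # SubjectRecord-like rows that passed QC
    excluded: list[tuple[str, str]]  # (subject id, reason)
    mask: GrayMatterMask
    gfc_stack: np.ndarray  # included subjects x mask voxels
    stat_map: object  # GroupStatMap
    clusters: list[ClusterResult]
    demographics: dict
    correlations: list[dict]
    classification: list[ClassificationReport]
    roc: list[ROCReport]
    preprocess_reports: dict[str, dict]
    provenance: dict = field(default_factory=dict)


def _spec_from_config(cfg: PipelineConfig) -> CohortSpec:
    s = cfg.simulate
    return CohortSpec(
        n_patients=s.n_patients,
        n_controls=s.n_controls,
        grid_shape=tuple(s.grid_shape),
        voxel_size=s.voxel_size,
        n_volumes=s.n_volumes,
        tr=s.tr,
        global_coupling_control=s.global_coupling_control,
        global_coupling_patient_effect=s.global_coupling_patient_effect,
        regional_coupling=s.regional_coupling,
        coupling_jitter_sd=s.coupling_jitter_sd,
        noise_sd=s.noise_sd,
        duration_slope=s.duration_slope,
        duration_noise_sd=s.duration_noise_sd,
        spike_rate=s.spike_rate,
        seed=cfg.seed,
    )


def _provenance(cfg: PipelineConfig) -> dict:
    """Analysis settings only: I/O paths are environment, not analysis,
    so they are excluded and identical runs hash identically."""
    settings = cfg.to_dict()
    settings.pop("data_dir", None)
    settings.pop("out_dir", None)
    return {
        "config": settings,
        "config_hash": hashlib.sha256(
            json.dumps(settings, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "seed": cfg.seed,
        "version": __version__,
    }


def _demographics(records: list) -> dict:
    pat = [r for r in records if r.group == "patient"]
    con = [r for r in records if r.group == "control"]
    out: dict = {"n_patients": len(pat), "n_controls": len(con)}
    if not pat or not con:
        return out
    for name, attr in (("age", "age"), ("education", "education_years"),
                       ("mean_fd", "mean_fd")):
        x = np.array([getattr(r, attr) for r in pat], dtype=float)
        y = np.array([getattr(r, attr) for r in con], dtype=float)
        t, df, p = two_sample_ttest(x, y)
        out[name] = {
            "patient_mean": round(float(x.mean()), 2),
            "patient_sd": round(float(x.std(ddof=1)), 2),
            "control_mean": round(float(y.mean()), 2),
            "control_sd": round(float(y.std(ddof=1)), 2),
            "t": round(t, 3), "df": df, "p": round(p, 4),
        }
    table = np.array(
        [[sum(r.sex == "male" for r in g), sum(r.sex == "female" for r in g)]
         for g in (pat, con)]
    )
    if (table.sum(axis=0) > 0).all():
        chi2, df_c, p_c = chi_square_test(table)
        out["sex"] = {
            "table": table.tolist(), "chi2": round(float(chi2), 4),
            "df": df_c, "p": round(float(p_c), 4),
        }
    durations = [r.duration_months for r in pat if r.duration_months is not None]
    if durations:
        d = np.array(durations, dtype=float)
        out["duration_months"] = {
            "mean": round(float(d.mean()), 2),
            "sd": round(float(d.std(ddof=1)), 2),
        }
    return out


@dataclass
class _IncludedSubject:
    id: str
    group: str
    age: int
    sex: str
    education_years: int
    duration_months: int | None
    mean_fd: float


def analyze_cohort(
    cohort: SyntheticCohort,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run preprocessing through classification on an in-memory cohort."""
    cfg = cfg or PipelineConfig()
    pp = cfg.preprocess
    mask = build_gm_mask(cohort.gm_prob, cfg.gfc.gm_threshold)

    included: list[_IncludedSubject] = []
    excluded: list[tuple[str, str]] = []
    reports: dict[str, dict] = {}
    maps = []
    t0 = time.time()
    for rec in cohort.subjects:
        vol = cohort.subject_image(rec)
        motion = cohort.subject_motion(rec)
        ts, report = preprocess_subject(
            vol, motion, mask, cohort.wm_mask, cohort.csf_mask,
            k_drop=pp.k_drop, fwhm_mm=pp.fwhm_mm, band=tuple(pp.band),
            fd_threshold=pp.fd_threshold,
            fd_sphere_radius_mm=pp.fd_sphere_radius_mm,
            max_trans_mm=pp.max_trans_mm, max_rot_deg=pp.max_rot_deg,
            scrub_floor=pp.scrub_floor, erode_wm=pp.erode_wm,
        )
        reports[rec.id] = report
        if ts is None:
            reason = report.get("exclusion_reason", "preprocessing failed")
            excluded.append((rec.id, reason))
            logger.info("excluding %s: %s", rec.id, reason)
            continue
        gmap = gfc_fast(
            ts, mode=cfg.gfc.mode, include_self=cfg.gfc.include_self,
            block_size=cfg.gfc.block_size,
        )
        maps.append(gmap.values)
        included.append(_IncludedSubject(
            id=rec.id, group=rec.group, age=rec.age, sex=rec.sex,
            education_years=rec.education_years,
            duration_months=rec.duration_months,
            mean_fd=report["mean_fd"],
        ))
    logger.info(
        "preprocess+gfc: %d subjects (%d excluded) in %.1f s",
        len(included), len(excluded), time.time() - t0,
    )
    if len(included) < 4:
        raise ValueError("too few subjects passed QC for group inference")
    gfc_stack = np.vstack(maps)

    group = np.array([1.0 if s.group == "patient" else 0.0 for s in included])
    if group.all() or not group.any():
        raise ValueError("need both groups after QC exclusions")
    design, labels = build_group_design(
        group,
        np.array([s.mean_fd for s in included]),
        np.array([s.age for s in included], dtype=float),
    )
    t0 = time.time()
    stat_map = permutation_fwe(
        gfc_stack, design, labels,
        n_perm=cfg.inference.n_perm, alpha=cfg.inference.alpha,
        seed=cfg.seed + 1,
    )
    logger.info("permutation inference (%d perms) in %.1f s",
                cfg.inference.n_perm, time.time() - t0)
    sig3d = map_to_volume(stat_map.sig_mask.astype(float), mask) > 0.5
    t3d = map_to_volume(stat_map.t, mask)
    clusters = extract_clusters(
        sig3d, t3d, mask.affine, cfg.inference.connectivity
    )

    correlations: list[dict] = []
    classification: list[ClassificationReport] = []
    roc_reports: list[ROCReport] = []
    if clusters:
        features = cluster_means(gfc_stack, clusters, mask.voxel_coords())
        pat_rows = np.array([s.group == "patient" for s in included])
        durations = np.array([
            s.duration_months if s.duration_months is not None else np.nan
            for s in included
        ])
        raw_p = []
        for k, cluster in enumerate(clusters):
            ok = pat_rows & np.isfinite(durations)
            if ok.sum() >= 3 and np.std(features[ok, k]) > 0:
                res = pearson_corr(features[ok, k], durations[ok])
                correlations.append({
                    "cluster_id": cluster.cluster_id, "r": res.r,
                    "p": res.p, "n": res.n,
                })
                raw_p.append(res.p)
        if raw_p:
            adj = bonferroni(raw_p)
            for row, pa in zip(correlations, adj):
                row["p_bonferroni"] = float(pa)

        cls_cfg = cfg.classify
        lc = np.arange(cls_cfg.log2_c_min, cls_cfg.log2_c_max + 1,
                       cls_cfg.grid_step, dtype=float)
        lg = np.arange(cls_cfg.log2_gamma_min, cls_cfg.log2_gamma_max + 1,
                       cls_cfg.grid_step, dtype=float)
        for k, cluster in enumerate(clusters):
            rid = f"cluster_{cluster.cluster_id}"
            classification.append(loocv_svm(
                features[:, k], pat_rows, region_id=rid,
                log2_c=lc, log2_gamma=lg, nested=cls_cfg.nested,
            ))
            roc_reports.append(roc_curve(
                features[:, k], pat_rows,
                direction=cls_cfg.roc_direction, region_id=rid,
            ))

    result = PipelineResult(
        included=included,
        excluded=excluded,
        mask=mask,
        gfc_stack=gfc_stack,
        stat_map=stat_map,
        clusters=clusters,
        demographics=_demographics(included),
        correlations=correlations,
        classification=classification,
        roc=roc_reports,
        preprocess_reports=reports,
        provenance=_provenance(cfg),
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _cluster_table(clusters: list[ClusterResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "size_voxels": c.size,
                "peak_x_mm": c.peak_mm[0],
                "peak_y_mm": c.peak_mm[1],
                "peak_z_mm": c.peak_mm[2],
                "peak_t": round(c.peak_t, 4),
                "direction": c.direction,
            }
            for c in clusters
        ],
        columns=["cluster_id", "size_voxels", "peak_x_mm", "peak_y_mm",
                 "peak_z_mm", "peak_t", "direction"],
    )


def _write_artifacts(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    mask = result.mask
    write_volume3d(mask.data, mask.affine, out / "gm_mask.nii.gz")
    write_volume3d(map_to_volume(result.stat_map.t, mask), mask.affine,
                   out / "t_map.nii.gz")
    write_volume3d(map_to_volume(result.stat_map.p_fwe, mask, fill=1.0),
                   mask.affine, out / "p_fwe.nii.gz")
    _cluster_table(result.clusters).to_csv(
        out / "cluster_table.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        result.correlations,
        columns=["cluster_id", "r", "p", "p_bonferroni", "n"],
    ).to_csv(out / "roi_correlations.tsv", sep="\t", index=False)
    with open(out / "demographics_report.json", "w") as fh:
        json.dump(result.demographics, fh, indent=1)
    with open(out / "classification_report.json", "w") as fh:
        json.dump([c.to_dict() for c in result.classification], fh, indent=1)
    with open(out / "roc_report.json", "w") as fh:
        json.dump([r.to_dict() for r in result.roc], fh, indent=1)
    with open(out / "preprocess_report.json", "w") as fh:
        json.dump(result.preprocess_reports, fh, indent=1)
    with open(out / "exclusions.json", "w") as fh:
        json.dump([{"id": i, "reason": r} for i, r in result.excluded], fh,
                  indent=1)
    with open(out / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=1)


class _DiskCohort:
    """Adapter presenting an on-disk cohort layout as a SyntheticCohort."""

    def __init__(self, data_dir: Path, cfg: PipelineConfig):
        self.dir = data_dir
        self.cfg = cfg
        self.gm_prob = read_prob_map(data_dir / "gm_prob.nii.gz")
        wm = read_prob_map(data_dir / "wm_mask.nii.gz")
        csf = read_prob_map(data_dir / "csf_mask.nii.gz")
        self.wm_mask = wm.data > 0.5
        self.csf_mask = csf.data > 0.5
        table = pd.read_csv(data_dir / "participants.tsv", sep="\t")
        self.subjects = []
        for _, row in table.iterrows():
            dur = row.get("duration_months")
            self.subjects.append(_DiskSubject(
                id=str(row["id"]), group=str(row["group"]),
                age=int(row["age"]), sex=str(row["sex"]),
                education_years=int(row["education_years"]),
                duration_months=(
                    None if pd.isna(dur) or dur == "" else int(dur)
                ),
            ))

    def subject_image(self, rec):
        path = self.dir / f"{rec.id}_bold.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"missing input {path}")
        return read_volume4d(path, tr=self.cfg.tr_fallback)

    def subject_motion(self, rec):
        path = self.dir / f"{rec.id}_motion.txt"
        if not path.exists():
            raise FileNotFoundError(f"missing input {path}")
        return MotionParams.from_file(
            path, rotation_unit=self.cfg.preprocess.rotation_unit
        )


@dataclass
class _DiskSubject:
    id: str
    group: str
    age: int
    sex: str
    education_years: int
    duration_months: int | None


def run_pipeline(
    cfg: PipelineConfig, simulate: bool = True
) -> tuple[Path, PipelineResult]:
    """Disk-based end-to-end run; returns (run directory, result).

    With ``simulate=True`` the synthetic cohort is written into
    ``cfg.data_dir`` first (skipped when the layout already exists, so
    runs are resumable); the analysis then reads everything back from
    disk exactly as it would for externally supplied data.
    """
    data_dir = Path(cfg.data_dir)
    if simulate:
        if (data_dir / "participants.tsv").exists():
            logger.info("reusing existing simulated cohort in %s", data_dir)
        else:
            write_cohort(generate_cohort(_spec_from_config(cfg)), data_dir)
    if not (data_dir / "participants.tsv").exists():
        raise FileNotFoundError(f"missing input {data_dir / 'participants.tsv'}")
    cohort = _DiskCohort(data_dir, cfg)
    out = Path(cfg.out_dir)
    result = analyze_cohort(cohort, cfg, out_dir=out)
    make_report(out, result)
    return out, result


class StagedRunner:
    """Resumable stage-by-stage execution behind the CLI.

    Every stage writes its artifacts into the run directory and is
    skipped when those artifacts already exist, so a run can be resumed
    or an individual stage re-executed after deleting its outputs.
    """

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.data_dir = Path(cfg.data_dir)
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)

    # -- stage: simulate ------------------------------------------------
    def simulate(self) -> Path:
        if (self.data_dir / "participants.tsv").exists():
            logger.info("simulate: cohort already present, skipping")
            return self.data_dir
        t0 = time.time()
        write_cohort(generate_cohort(_spec_from_config(self.cfg)), self.data_dir)
        logger.info("simulate: wrote %s in %.1f s", self.data_dir,
                    time.time() - t0)
        return self.data_dir

    def _cohort(self) -> "_DiskCohort":
        if not (self.data_dir / "participants.tsv").exists():
            raise FileNotFoundError(
                f"missing input {self.data_dir / 'participants.tsv'}"
            )
        return _DiskCohort(self.data_dir, self.cfg)

    # -- stage: preprocess ----------------------------------------------
    def preprocess(self) -> Path:
        prep_dir = self.out / "prep"
        prep_dir.mkdir(exist_ok=True)
        cohort = self._cohort()
        pp = self.cfg.preprocess
        mask = build_gm_mask(cohort.gm_prob, self.cfg.gfc.gm_threshold)
        reports = {}
        for rec in cohort.subjects:
            target = prep_dir / f"{rec.id}.npz"
            if target.exists():
                logger.info("preprocess: %s cached", rec.id)
                continue
            ts, report = preprocess_subject(
                cohort.subject_image(rec), cohort.subject_motion(rec),
                mask, cohort.wm_mask, cohort.csf_mask,
                k_drop=pp.k_drop, fwhm_mm=pp.fwhm_mm, band=tuple(pp.band),
                fd_threshold=pp.fd_threshold,
                fd_sphere_radius_mm=pp.fd_sphere_radius_mm,
                max_trans_mm=pp.max_trans_mm, max_rot_deg=pp.max_rot_deg,
                scrub_floor=pp.scrub_floor, erode_wm=pp.erode_wm,
            )
            reports[rec.id] = report
            if ts is None:
                np.savez(target, excluded=np.array([1]),
                         mean_fd=report["mean_fd"])
            else:
                np.savez(target, values=ts.values, excluded=np.array([0]),
                         mean_fd=report["mean_fd"])
            logger.info("preprocess: %s done (qc %s)", rec.id,
                        "pass" if ts is not None else "FAIL")
        report_path = self.out / "preprocess_report.json"
        if reports or not report_path.exists():
            existing = {}
            if report_path.exists():
                existing = json.loads(report_path.read_text())
            existing.update(reports)
            report_path.write_text(json.dumps(existing, indent=1))
        return prep_dir

    # -- stage: gfc -----------------------------------------------------
    def gfc(self) -> Path:
        target = self.out / "gfc_stack.npz"
        if target.exists():
            logger.info("gfc: cached")
            return target
        self.preprocess()
        cohort = self._cohort()
        mask = build_gm_mask(cohort.gm_prob, self.cfg.gfc.gm_threshold)
        maps, ids, fds = [], [], []
        for rec in cohort.subjects:
            with np.load(self.out / "prep" / f"{rec.id}.npz") as z:
                if int(z["excluded"][0]):
                    continue
                values = z["values"]
                fds.append(float(z["mean_fd"]))
            gmap = gfc_fast(
                values, mode=self.cfg.gfc.mode,
                include_self=self.cfg.gfc.include_self,
                block_size=self.cfg.gfc.block_size,
            )
            write_volume3d(map_to_volume(gmap.values, mask), mask.affine,
                           self.out / f"{rec.id}_gfc.nii.gz")
            maps.append(gmap.values)
            ids.append(rec.id)
        stack = np.vstack(maps)
        np.savez(target, stack=stack, ids=np.array(ids),
                 mean_fd=np.array(fds))
        # cohort-level 4D stack (one frame per subject) for inspection
        stack4d = np.stack(
            [map_to_volume(m, mask) for m in stack], axis=-1
        )
        write_volume4d(
            Volume4D(data=stack4d, affine=mask.affine, tr=1.0),
            self.out / "gfc_stack.nii.gz",
        )
        logger.info("gfc: %d subject maps", len(ids))
        return target

    def _load_stack(self):
        self.gfc()
        cohort = self._cohort()
        with np.load(self.out / "gfc_stack.npz") as z:
            stack, ids, fds = z["stack"], list(z["ids"]), z["mean_fd"]
        by_id = {r.id: r for r in cohort.subjects}
        records = [by_id[str(i)] for i in ids]
        mask = build_gm_mask(cohort.gm_prob, self.cfg.gfc.gm_threshold)
        return stack, records, fds, mask

    # -- stage: group ---------------------------------------------------
    def group(self) -> Path:
        target = self.out / "cluster_table.tsv"
        if target.exists() and (self.out / "clusters.json").exists():
            logger.info("group: cached")
            return target
        stack, records, fds, mask = self._load_stack()
        group = np.array([1.0 if r.group == "patient" else 0.0
                          for r in records])
        design, labels = build_group_design(
            group, fds, np.array([r.age for r in records], dtype=float)
        )
        stat_map = permutation_fwe(
            stack, design, labels, n_perm=self.cfg.inference.n_perm,
            alpha=self.cfg.inference.alpha, seed=self.cfg.seed + 1,
        )
        sig3d = map_to_volume(stat_map.sig_mask.astype(float), mask) > 0.5
        t3d = map_to_volume(stat_map.t, mask)
        clusters = extract_clusters(sig3d, t3d, mask.affine,
                                    self.cfg.inference.connectivity)
        write_volume3d(t3d, mask.affine, self.out / "t_map.nii.gz")
        write_volume3d(map_to_volume(stat_map.p_fwe, mask, fill=1.0),
                       mask.affine, self.out / "p_fwe.nii.gz")
        _cluster_table(clusters).to_csv(target, sep="\t", index=False)
        with open(self.out / "clusters.json", "w") as fh:
            json.dump([
                {"cluster_id": c.cluster_id,
                 "members": c.member_voxels.tolist(),
                 "peak_t": c.peak_t, "peak_mm": list(c.peak_mm),
                 "direction": c.direction}
                for c in clusters
            ], fh)
        logger.info("group: %d significant cluster(s)", len(clusters))
        return target

    def _features(self):
        self.group()
        stack, records, fds, mask = self._load_stack()
        with open(self.out / "clusters.json") as fh:
            raw = json.load(fh)
        clusters = [
            ClusterResult(
                cluster_id=c["cluster_id"],
                member_voxels=np.array(c["members"], dtype=int),
                size=len(c["members"]),
                peak_voxel=(0, 0, 0), peak_mm=tuple(c["peak_mm"]),
                peak_t=c["peak_t"], direction=c["direction"],
            )
            for c in raw
        ]
        features = (
            cluster_means(stack, clusters, mask.voxel_coords())
            if clusters else np.empty((stack.shape[0], 0))
        )
        return features, clusters, records

    # -- stage: correlate -----------------------------------------------
    def correlate(self) -> Path:
        target = self.out / "roi_correlations.tsv"
        if target.exists():
            logger.info("correlate: cached")
            return target
        features, clusters, records = self._features()
        rows = []
        pat = np.array([r.group == "patient" for r in records])
        dur = np.array([
            r.duration_months if r.duration_months is not None else np.nan
            for r in records
        ])
        ok = pat & np.isfinite(dur)
        for k, c in enumerate(clusters):
            if ok.sum() >= 3 and np.std(features[ok, k]) > 0:
                res = pearson_corr(features[ok, k], dur[ok])
                rows.append({"cluster_id": c.cluster_id, "r": res.r,
                             "p": res.p, "n": res.n})
        if rows:
            adj = bonferroni([r["p"] for r in rows])
            for row, pa in zip(rows, adj):
                row["p_bonferroni"] = float(pa)
        pd.DataFrame(
            rows, columns=["cluster_id", "r", "p", "p_bonferroni", "n"]
        ).to_csv(target, sep="\t", index=False)
        logger.info("correlate: %d cluster correlation(s)", len(rows))
        return target

    # -- stage: classify ------------------------------------------------
    def classify(self) -> Path:
        target = self.out / "classification_report.json"
        if target.exists():
            logger.info("classify: cached")
            return target
        features, clusters, records = self._features()
        pat = np.array([r.group == "patient" for r in records])
        cc = self.cfg.classify
        lc = np.arange(cc.log2_c_min, cc.log2_c_max + 1, cc.grid_step,
                       dtype=float)
        lg = np.arange(cc.log2_gamma_min, cc.log2_gamma_max + 1,
                       cc.grid_step, dtype=float)
        cls, rocs = [], []
        for k, c in enumerate(clusters):
            rid = f"cluster_{c.cluster_id}"
            cls.append(loocv_svm(features[:, k], pat, region_id=rid,
                                 log2_c=lc, log2_gamma=lg, nested=cc.nested))
            rocs.append(roc_curve(features[:, k], pat,
                                  direction=cc.roc_direction, region_id=rid))
        with open(target, "w") as fh:
            json.dump([c.to_dict() for c in cls], fh, indent=1)
        with open(self.out / "roc_report.json", "w") as fh:
            json.dump([r.to_dict() for r in rocs], fh, indent=1)
        logger.info("classify: %d region report(s)", len(cls))
        return target

    # -- stage: report --------------------------------------------------
    def report(self) -> Path:
        self.correlate()
        self.classify()
        result = self._assemble_result()
        make_report(self.out, result)
        logger.info("report: tables written to %s", self.out)
        return self.out / "summary.json"

    def run_all(self) -> Path:
        self.simulate()
        self.preprocess()
        self.gfc()
        self.group()
        self.correlate()
        self.classify()
        return self.report()

    def _assemble_result(self) -> PipelineResult:
        features, clusters, records = self._features()
        stack, recs, fds, mask = self._load_stack()
        pat = np.array([r.group == "patient" for r in recs])
        corr = pd.read_csv(self.out / "roi_correlations.tsv", sep="\t")
        with open(self.out / "classification_report.json") as fh:
            cls_raw = json.load(fh)
        with open(self.out / "roc_report.json") as fh:
            roc_raw = json.load(fh)
        cls = [
            ClassificationReport(
                region_id=d["region_id"],
                log2_c=np.array(d["log2_c"]),
                log2_gamma=np.array(d["log2_gamma"]),
                accuracy_grid=np.array(d["accuracy_grid"]),
                best_log2_c=d["best_log2_c"],
                best_log2_gamma=d["best_log2_gamma"],
                best_accuracy=d["best_accuracy"],
                tp=d["confusion"]["tp"], fn=d["confusion"]["fn"],
                tn=d["confusion"]["tn"], fp=d["confusion"]["fp"],
                metrics=d["metrics"],
            )
            for d in cls_raw
        ]
        rocs = [
            ROCReport(
                region_id=d["region_id"], auc=d["auc"], cutoff=d["cutoff"],
                sensitivity=d["sensitivity"], specificity=d["specificity"],
                thresholds=np.array(d["thresholds"]),
                sens_sweep=np.array(d["sens_sweep"]),
                spec_sweep=np.array(d["spec_sweep"]),
                direction=d["direction"],
            )
            for d in roc_raw
        ]
        included = [
            _IncludedSubject(
                id=r.id, group=r.group, age=r.age, sex=r.sex,
                education_years=r.education_years,
                duration_months=r.duration_months, mean_fd=float(fd),
            )
            for r, fd in zip(recs, fds)
        ]
        all_ids = {r.id for r in self._cohort().subjects}
        reasons = {}
        report_path = self.out / "preprocess_report.json"
        if report_path.exists():
            for sid, rep in json.loads(report_path.read_text()).items():
                if "exclusion_reason" in rep:
                    reasons[sid] = rep["exclusion_reason"]
        excluded = [(i, reasons.get(i, "excluded during preprocessing"))
                    for i in sorted(all_ids - {r.id for r in recs})]
        return PipelineResult(
            included=included, excluded=excluded, mask=mask,
            gfc_stack=stack, stat_map=None, clusters=clusters,
            demographics=_demographics(included),
            correlations=corr.to_dict("records"),
            classification=cls, roc=rocs, preprocess_reports={},
            provenance=_provenance(self.cfg),
        )


def _fmt_pct(pct: float, num: int, den: int) -> str:
    return f"{pct:.2f}% ({num}/{den})"


def make_report(run_dir: str | Path, result: PipelineResult) -> dict:
    """Emit the four summary tables (TSV) and a combined JSON summary."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    demo = result.demographics
    rows = []
    for key, label in (("age", "Age (years)"),
                       ("education", "Education (years)"),
                       ("mean_fd", "FD (mm)")):
        if key in demo:
            d = demo[key]
            rows.append({
                "variable": label,
                "patients": f"{d['patient_mean']} ± {d['patient_sd']}",
                "controls": f"{d['control_mean']} ± {d['control_sd']}",
                "p_value": d["p"],
            })
    if "sex" in demo:
        t = demo["sex"]["table"]
        rows.insert(0, {
            "variable": "Sex (male/female)",
            "patients": f"{t[0][0]}/{t[0][1]}",
            "controls": f"{t[1][0]}/{t[1][1]}",
            "p_value": demo["sex"]["p"],
        })
    if "duration_months" in demo:
        d = demo["duration_months"]
        rows.append({
            "variable": "Illness duration (months)",
            "patients": f"{d['mean']} ± {d['sd']}",
            "controls": "", "p_value": "",
        })
    pd.DataFrame(rows).to_csv(run_dir / "table1_demographics.tsv",
                              sep="\t", index=False)
    with open(run_dir / "demographics_report.json", "w") as fh:
        json.dump(demo, fh, indent=1)
    _cluster_table(result.clusters).to_csv(
        run_dir / "table2_clusters.tsv", sep="\t", index=False
    )
    cls_rows = []
    for rep in result.classification:
        n_pos = rep.tp + rep.fn
        n_neg = rep.tn + rep.fp
        cls_rows.append({
            "region": rep.region_id,
            "accuracy": _fmt_pct(rep.metrics["accuracy_pct"],
                                 rep.tp + rep.tn, n_pos + n_neg),
            "sensitivity": _fmt_pct(rep.metrics["sensitivity_pct"],
                                    rep.tp, n_pos),
            "specificity": _fmt_pct(rep.metrics["specificity_pct"],
                                    rep.tn, n_neg),
        })
    pd.DataFrame(
        cls_rows, columns=["region", "accuracy", "sensitivity", "specificity"]
    ).to_csv(run_dir / "table3_classification.tsv", sep="\t", index=False)
    roc_rows = []
    for rep in result.roc:
        roc_rows.append({
            "region": rep.region_id,
            "auc": round(rep.auc, 3),
            "cutoff": round(rep.cutoff, 4),
            "sensitivity_pct": round(rep.sensitivity, 2),
            "specificity_pct": round(rep.specificity, 2),
        })
    pd.DataFrame(
        roc_rows,
        columns=["region", "auc", "cutoff", "sensitivity_pct",
                 "specificity_pct"],
    ).to_csv(run_dir / "table4_roc.tsv", sep="\t", index=False)
    summary = {
        "n_included": len(result.included),
        "n_excluded": len(result.excluded),
        "n_clusters": len(result.clusters),
        "demographics": demo,
        "correlations": result.correlations,
        "classification": [c.to_dict() for c in result.classification],
        "roc": [r.to_dict() for r in result.roc],
        "provenance": result.provenance,
    }
    with open(run_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
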