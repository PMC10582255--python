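"""End-to-end orchestration of the M_GMV pipeline.

Stage order mirrors the analysis: TIV-normalize -> harmonize -> group-level
ROI scan -> M_GMV scoring -> progression regression -> SP/FP classification.
Each stage is also callable on its own; ``run_pipeline`` chains them,
writes every intermediate table and a JSON manifest, and is deterministic
given the master seed.
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

from . import classify as clf
from .association import AssociationScanResult, roi_association_scan
from .cohort import (ROIVolumeTable, SubjectRecord, validate_cohort,
                     write_cohort)
from .distance import (MGMVResult, build_reference_ensemble,
                       fit_residual_model, residualize, score_patients)
from .harmonization import apply_combat, fit_combat
from .outcomes import OutcomeDelta, compute_deltas, normalize_tiv
from .regression import fit_progression_model, progression_table
from .synthetic import SyntheticConfig, generate_cohort

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "covariate_design",
           "harmonized_gmvn", "mgmv_scores", "regression_r2_on_cohort",
           "classification_run"]

OUTCOME_NAMES = ("total", "rigidity", "bradykinesia", "pig",
                 "postural_kinetic", "rest")


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    synthetic: SyntheticConfig | None = None   # else read from input paths
    subjects_path: Path | None = None
    volumes_path: Path | None = None
    motor_path: Path | None = None
    harmonize: bool = True
    m: int = 100
    B: int = 1000
    test_fraction: float = 0.3
    cv_folds: int = 10
    grid: dict = field(default_factory=lambda: dict(clf.DEFAULT_GRID))


def covariate_design(subjects: list[SubjectRecord]) -> np.ndarray:
    """(diagnosis PD=1, age, sex male=1) design, no intercept."""
    return np.column_stack([
        np.array([1.0 if s.group == "PD" else 0.0 for s in subjects]),
        np.array([s.age for s in subjects]),
        np.array([1.0 if s.sex == "male" else 0.0 for s in subjects]),
    ])


def harmonized_gmvn(subjects: list[SubjectRecord], volumes: ROIVolumeTable,
                    harmonize: bool = True):
    """TIV-normalize and (optionally) harmonize; rows follow ``volumes``."""
    norm = normalize_tiv(volumes)
    if not harmonize:
        return norm.volumes, None
    order = {s.subject_id: s for s in subjects}
    subs = [order[sid] for sid in norm.subject_ids]
    site = np.array([s.site_id for s in subs])
    model = fit_combat(norm.volumes, site, covariate_design(subs))
    return apply_combat(model, norm.volumes, site,
                        covariate_design(subs)), model


def mgmv_scores(subjects: list[SubjectRecord], harmonized: np.ndarray,
                subject_ids: list[str], m: int = 100, B: int = 1000,
                seed: int | None = None, fit_on: str = "hc",
                ) -> list[MGMVResult]:
    """Age-residualize (controls-fit model) and score all PD subjects."""
    info = {s.subject_id: s for s in subjects}
    ages = np.array([info[sid].age for sid in subject_ids])
    is_hc = np.array([info[sid].group == "HC" for sid in subject_ids])
    fit_rows = slice(None) if fit_on == "all" else is_hc
    model = fit_residual_model(harmonized[fit_rows], ages[fit_rows])
    resid = residualize(model, harmonized, ages)
    ensemble = build_reference_ensemble(resid[is_hc], m=m, B=B, seed=seed)
    pd_ids = [sid for sid, h in zip(subject_ids, is_hc) if not h]
    return score_patients(resid[~is_hc], pd_ids, ensemble, seed=seed)


def _delta_frame(deltas: list[OutcomeDelta]) -> pd.DataFrame:
    return pd.DataFrame([{"subject_id": d.subject_id,
                          **{k: v for k, v in d.as_dict().items()}}
                         for d in deltas]).set_index("subject_id")


def regression_r2_on_cohort(cfg: SyntheticConfig, seed: int,
                            B: int = 100, m: int = 100) -> float:
    """Adjusted R² of the M_GMV total-change regression on one cohort.

    Fast path used by the generator's calibration loop and by replicate
    studies; runs the real pipeline end-to-end at a reduced ensemble size.
    """
    subjects, volumes, assessments, _ = generate_cohort(cfg, seed=seed)
    harmonized, _ = harmonized_gmvn(subjects, volumes, harmonize=True)
    results = mgmv_scores(subjects, harmonized, volumes.subject_ids,
                          m=m, B=B, seed=seed)
    deltas = {d.subject_id: d for d in compute_deltas(assessments)}
    info = {s.subject_id: s for s in subjects}
    mg = np.array([r.m_gmv for r in results])
    ids = [r.subject_id for r in results]
    fit = fit_progression_model(
        mg, [info[i].age for i in ids],
        [1.0 if info[i].sex == "male" else 0.0 for i in ids],
        [deltas[i].delta_total for i in ids])
    return fit.r2_adj


def classification_run(features: np.ndarray, labels: np.ndarray,
                       seed: int | None = None, test_fraction: float = 0.3,
                       cv_folds: int = 10, grid: dict | None = None,
                       ) -> clf.ClassificationReport:
    """Split, standardize on train, grid-search the SVM, evaluate held-out."""
    train, test = clf.split_train_test(len(labels), test_fraction, seed=seed)
    z, _ = clf.standardize(features, train)
    model = clf.train_svm(z[train], labels[train], cv_folds=cv_folds,
                          grid=grid, seed=seed)
    return clf.evaluate(model, z[test], labels[test], seed=seed)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, writing intermediates and a run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "files": {}}
    t0 = time.time()

    def stage(name):
        manifest["stages"].append(
            {"name": name, "elapsed_s": round(time.time() - t0, 3)})
        log.info("stage complete: %s", name)

    # inputs
    if config.synthetic is not None:
        subjects, volumes, assessments, truth = generate_cohort(
            config.synthetic, seed=config.seed)
        write_cohort(subjects, volumes, assessments,
                     out / "subjects.csv", out / "volumes.csv",
                     out / "motor.csv")
    else:
        from .cohort import read_cohort
        subjects, volumes, assessments = read_cohort(
            config.subjects_path, config.volumes_path, config.motor_path)
    report = validate_cohort(subjects, volumes, assessments)
    (out / "validation.json").write_text(report.to_json())
    if not report.passed:
        raise RuntimeError("stage 'validate' failed: cohort invalid "
                           f"({report.messages[:3]})")
    stage("validate")

    harmonized, _hmodel = harmonized_gmvn(subjects, volumes,
                                          config.harmonize)
    hdf = pd.DataFrame(harmonized, columns=volumes.roi_names)
    hdf.insert(0, "subject_id", volumes.subject_ids)
    hdf.to_csv(out / "harmonized_gmvn.csv", index=False)
    stage("harmonize")

    info = {s.subject_id: s for s in subjects}
    deltas = compute_deltas(
        assessments, [s.subject_id for s in subjects if s.group == "PD"])
    ddf = _delta_frame(deltas)
    ddf.to_csv(out / "outcome_deltas.csv")
    stage("outcomes")

    pd_ids = [d.subject_id for d in deltas]
    rows = {sid: volumes.subject_ids.index(sid) for sid in pd_ids}
    confounds = pd.DataFrame({
        "age": [info[i].age for i in pd_ids],
        "sex": [1.0 if info[i].sex == "male" else 0.0 for i in pd_ids],
        "disease_duration": [info[i].disease_duration for i in pd_ids],
    })
    scan: AssociationScanResult = roi_association_scan(
        harmonized[[rows[i] for i in pd_ids]], volumes.roi_names,
        ddf.loc[pd_ids], confounds)
    scan.to_csv(out / "roi_association_scan.csv")
    stage("group_scan")

    results = mgmv_scores(subjects, harmonized, volumes.subject_ids,
                          m=config.m, B=config.B, seed=config.seed)
    mg = pd.DataFrame([{"subject_id": r.subject_id, "m_gmv": r.m_gmv,
                        "B": r.B, "m": r.m, "seed": config.seed}
                       for r in results]).set_index("subject_id")
    mg.to_csv(out / "m_gmv.csv")
    stage("m_gmv")

    reg_results = []
    mgv = mg.loc[pd_ids, "m_gmv"].to_numpy()
    age = confounds["age"].to_numpy()
    sex = confounds["sex"].to_numpy()
    for outcome in OUTCOME_NAMES:
        reg_results.append(fit_progression_model(
            mgv, age, sex, ddf.loc[pd_ids, outcome].to_numpy(),
            outcome=outcome))
    rt = progression_table(reg_results)
    rt.to_csv(out / "progression_regression.csv", index=False)
    stage("regression")

    labels = clf.median_split(pd_ids, ddf.loc[pd_ids, "total"].to_numpy())
    baseline_totals = {
        a.subject_id: a.total for a in assessments
        if a.timepoint == "baseline"}
    features = np.column_stack([
        mgv, age, sex, np.array([baseline_totals[i] for i in pd_ids])])
    creport = classification_run(features, labels.labels, seed=config.seed,
                                 test_fraction=config.test_fraction,
                                 cv_folds=config.cv_folds, grid=config.grid)
    (out / "classification.json").write_text(
        json.dumps(creport.as_dict(), indent=2))
    stage("classify")

    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if f.name != "manifest.json":
            manifest["files"][f.name] = _checksum(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"manifest": manifest, "regression": rt, "scan": scan,
            "classification": creport, "m_gmv": mg, "deltas": ddf,
            "labels": labels}
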