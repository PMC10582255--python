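"""Replicate studies over synthetic cohorts.

These functions re-run pipeline stages across many independently generated
cohorts to measure operating characteristics: the rate of null group-level
scans, the significance rate of the patient-level distance regression,
confidence-interval coverage for the generator's outcome slope, the
held-out distance calibration, and the classifier feature-ablation pattern.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .association import roi_association_scan
from .classify import median_split
from .distance import build_reference_ensemble, score_patients
from .outcomes import compute_deltas
from .pipeline import classification_run, harmonized_gmvn, mgmv_scores
from .regression import fit_progression_model
from .synthetic import SyntheticConfig, generate_cohort

__all__ = [
    "headline_rates", "slope_coverage", "held_out_distance_calibration",
    "feature_ablation_accuracies",
]


def _cohort_stats(cfg: SyntheticConfig, seed: int, B: int, m: int):
    subjects, volumes, assessments, truth = generate_cohort(cfg, seed=seed)
    harmonized, _ = harmonized_gmvn(subjects, volumes)
    info = {s.subject_id: s for s in subjects}
    deltas = {d.subject_id: d for d in compute_deltas(assessments)}
    results = mgmv_scores(subjects, harmonized, volumes.subject_ids,
                          m=m, B=B, seed=seed)
    pd_ids = [r.subject_id for r in results]
    rows = [volumes.subject_ids.index(i) for i in pd_ids]
    outcome_df = pd.DataFrame(
        {"total": [deltas[i].delta_total for i in pd_ids]})
    confounds = pd.DataFrame({
        "age": [info[i].age for i in pd_ids],
        "sex": [1.0 if info[i].sex == "male" else 0.0 for i in pd_ids],
        "disease_duration": [info[i].disease_duration for i in pd_ids]})
    scan = roi_association_scan(harmonized[rows], volumes.roi_names,
                                outcome_df, confounds)
    mg = np.array([r.m_gmv for r in results])
    reg = fit_progression_model(
        mg, confounds["age"].to_numpy(), confounds["sex"].to_numpy(),
        outcome_df["total"].to_numpy())
    return subjects, assessments, deltas, scan, reg, mg, pd_ids, info


def headline_rates(n_replicates: int = 50, B: int = 200, m: int = 100,
                   seed: int = 0, config: SyntheticConfig | None = None,
                   ) -> dict:
    """Rate of null ROI scans and of significant distance regressions.

    Mirrors the study's central contrast: per-ROI group-level associations
    stay below the Bonferroni bar while the patient-level multivariate
    distance predicts motor change at p < 0.05/6.
    """
    cfg = config or SyntheticConfig()
    null_scans = 0
    sig_regressions = 0
    r2s = []
    for r in range(n_replicates):
        *_, scan, reg, _, _, _ = _cohort_stats(
            cfg, seed=seed * 1_000_003 + r, B=B, m=m)
        null_scans += len(scan.significant_pairs) == 0
        sig_regressions += reg.p < 0.05 / 6
        r2s.append(reg.r2_adj)
    return {
        "null_scan_rate": null_scans / n_replicates,
        "significant_regression_rate": sig_regressions / n_replicates,
        "mean_r2_adj": float(np.mean(r2s)),
        "n_replicates": n_replicates,
    }


def slope_coverage(n_replicates: int = 500, seed: int = 0,
                   config: SyntheticConfig | None = None) -> dict:
    """95% CI coverage for the generator's outcome slope.

    Uses the regressor the generator's linear model actually holds for —
    the latent severity d_i — with baseline coupling off, so the fitted
    slope is unbiased for b1 and classical CIs should cover at ~95%.
    Integer realization of the motor scores adds rounding noise but no
    bias.
    """
    cfg = replace(config or SyntheticConfig(), baseline_coupling=0.0)
    covered = 0
    for r in range(n_replicates):
        s = seed * 2_000_003 + r
        subjects, volumes, assessments, truth = generate_cohort(cfg, seed=s)
        deltas = {d.subject_id: d for d in compute_deltas(assessments)}
        info = {x.subject_id: x for x in subjects}
        pd_ids = sorted(truth.severity)
        d = np.array([truth.severity[i] for i in pd_ids])
        reg = fit_progression_model(
            d, np.array([info[i].age for i in pd_ids]),
            np.array([1.0 if info[i].sex == "male" else 0.0
                      for i in pd_ids]),
            np.array([deltas[i].delta_total for i in pd_ids]))
        covered += reg.ci95[0] <= cfg.outcome_b1 <= reg.ci95[1]
    return {"coverage": covered / n_replicates,
            "true_slope": cfg.outcome_b1, "n_replicates": n_replicates}


def held_out_distance_calibration(p: int = 40, m: int = 100,
                                  pool_size: int = 120, B: int = 200,
                                  n_held_out: int = 1000,
                                  seed: int = 0) -> dict:
    """Mean squared distance of held-out MVN draws vs the Wishart expectation
    p(m-1)/(m-p-2) for a size-m reference."""
    rng = np.random.default_rng(seed)
    pool = rng.standard_normal((pool_size, p))
    held = rng.standard_normal((n_held_out, p))
    ensemble = build_reference_ensemble(pool, m=m, B=B, seed=seed)
    res = score_patients(held, [f"h{i}" for i in range(n_held_out)],
                         ensemble)
    msd = float(np.mean([np.mean(r.distances ** 2) for r in res]))
    expected = p * (m - 1) / (m - p - 2)
    return {"mean_squared_distance": msd, "expected": expected,
            "relative_error": abs(msd - expected) / expected}


def feature_ablation_accuracies(n_seeds: int = 20, B: int = 200,
                                m: int = 100, seed: int = 0,
                                config: SyntheticConfig | None = None,
                                ) -> dict:
    """Mean held-out accuracy for full, distance-only and clinical-only
    feature sets across independently generated cohorts."""
    cfg = config or SyntheticConfig()
    accs = {"full": [], "m_gmv_only": [], "clinical_only": []}
    for r in range(n_seeds):
        s = seed * 3_000_017 + r
        subjects, assessments, deltas, _, _, mg, pd_ids, info = \
            _cohort_stats(cfg, seed=s, B=B, m=m)
        baseline_totals = {a.subject_id: a.total for a in assessments
                           if a.timepoint == "baseline"}
        age = np.array([info[i].age for i in pd_ids])
        sex = np.array([1.0 if info[i].sex == "male" else 0.0
                        for i in pd_ids])
        base = np.array([baseline_totals[i] for i in pd_ids])
        labels = median_split(
            pd_ids, np.array([deltas[i].delta_total for i in pd_ids]))
        sets = {
            "full": np.column_stack([mg, age, sex, base]),
            "m_gmv_only": mg[:, None],
            "clinical_only": np.column_stack([age, sex, base]),
        }
        for name, X in sets.items():
            rep = classification_run(X, labels.labels, seed=s, cv_folds=10)
            accs[name].append(rep.accuracy)
    out = {k: float(np.mean(v)) for k, v in accs.items()}
    out["n_seeds"] = n_seeds
    return out
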