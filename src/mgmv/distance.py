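"""The multivariate gray-matter volumetric distance (M_GMV).

A patient's 40-ROI residual profile s is scored against a healthy-control
reference (mean mu, covariance C) with the Mahalanobis distance

    M_GMV = sqrt((s - mu)' C^{-1} (s - mu)),

a covariance-aware multivariate generalization of the z-score.  Because a
single 40 x 40 sample covariance from a finite control pool is noisy, the
reference is an ensemble: B random subsamples of m controls each (default
m = 100, B = 1000), and the patient's reported score is the median distance
across the ensemble.

Age is regressed out of GMV_N beforehand: an ordinary least-squares line
per ROI, fit on healthy controls only, is subtracted from every subject
(normative-modeling convention; a flag allows fitting on all subjects for
sensitivity analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "ResidualModel", "ReferenceDistribution", "MGMVResult",
    "fit_residual_model", "residualize", "mahalanobis",
    "build_reference_ensemble", "score_patients",
]

#: condition number above which a reference covariance triggers a warning
CONDITION_WARN = 1e10


@dataclass
class ResidualModel:
    """Per-ROI linear age model (intercept + slope), fit on controls."""

    intercept: np.ndarray   # (p,)
    slope: np.ndarray       # (p,)

    def predict(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        return self.intercept[None, :] + ages[:, None] * self.slope[None, :]


@dataclass
class ReferenceDistribution:
    """One control subsample's normative model: mu, C and its inverse."""

    member_ids: np.ndarray      # indices (or ids) of the m controls
    mu: np.ndarray              # (p,)
    cov: np.ndarray             # (p, p)
    cov_inv: np.ndarray         # (p, p)
    condition_number: float


@dataclass
class MGMVResult:
    subject_id: str
    distances: np.ndarray       # (B,)
    m_gmv: float
    B: int
    m: int
    seed: int | None = None


def fit_residual_model(values: np.ndarray, ages: np.ndarray) -> ResidualModel:
    """OLS of each ROI's GMV_N on age with intercept (control rows only)."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 controls to fit the age model")
    if np.ptp(ages) == 0:
        raise ValueError("constant age: slope not identifiable")
    X = np.column_stack([np.ones(len(ages)), ages])
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    return ResidualModel(intercept=coef[0], slope=coef[1])


def residualize(model: ResidualModel, values: np.ndarray,
                ages: np.ndarray) -> np.ndarray:
    """Subtract the control-fit age prediction from any subject's values."""
    return np.asarray(values, dtype=float) - model.predict(ages)


def mahalanobis(s: np.ndarray, ref: ReferenceDistribution) -> float:
    """Exact quadratic-form square root distance of s from the reference."""
    s = np.asarray(s, dtype=float)
    if s.shape != ref.mu.shape:
        raise ValueError(
            f"dimension mismatch: s has {s.shape}, reference {ref.mu.shape}")
    d = s - ref.mu
    q = float(d @ ref.cov_inv @ d)
    return float(np.sqrt(max(q, 0.0)))


def _make_reference(resid: np.ndarray, members: np.ndarray,
                    ) -> ReferenceDistribution | None:
    sub = resid[members]
    mu = sub.mean(axis=0)
    C = np.cov(sub, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    try:
        C_inv = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        return None
    if not np.allclose(C @ C_inv, np.eye(C.shape[0]), atol=1e-6):
        return None
    cond = float(np.linalg.cond(C))
    if cond > CONDITION_WARN:
        log.warning("reference covariance ill-conditioned (cond=%.2e)", cond)
    return ReferenceDistribution(member_ids=members, mu=mu, cov=C,
                                 cov_inv=C_inv, condition_number=cond)


def build_reference_ensemble(hc_residuals: np.ndarray, m: int = 100,
                             B: int = 1000, seed: int | None = None,
                             ) -> list[ReferenceDistribution]:
    """Draw B control subsamples of size m and build a reference from each.

    Sampling is without replacement within each draw and independent across
    draws.  A draw yielding a singular covariance is redrawn (counted and
    logged).  Fully deterministic given the seed; each draw uses its own
    RNG stream so results do not depend on evaluation order.
    """
    hc_residuals = np.asarray(hc_residuals, dtype=float)
    pool, p = hc_residuals.shape
    if pool < m:
        raise ValueError(f"control pool ({pool}) smaller than subsample m={m}")
    if m <= p:
        log.warning("subsample size m=%d <= %d ROIs: covariance singular "
                    "almost surely", m, p)
    root = np.random.SeedSequence(seed)
    streams = root.spawn(B)
    refs: list[ReferenceDistribution] = []
    redraws = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        while True:
            members = rng.choice(pool, size=m, replace=False)
            ref = _make_reference(hc_residuals, members)
            if ref is not None:
                refs.append(ref)
                break
            redraws += 1
            if redraws > 10 * B:
                raise RuntimeError("could not draw a nonsingular reference")
    if redraws:
        log.info("redrew %d singular reference subsample(s)", redraws)
    return refs


def score_patients(residuals: np.ndarray, subject_ids: list[str],
                   ensemble: list[ReferenceDistribution],
                   seed: int | None = None) -> list[MGMVResult]:
    """Median-over-ensemble Mahalanobis distance per patient.

    The median of an even-length distance vector is the midpoint of the two
    central order statistics (numpy convention).
    """
    residuals = np.asarray(residuals, dtype=float)
    B = len(ensemble)
    m = len(ensemble[0].member_ids) if B else 0
    out: list[MGMVResult] = []
    # stack references for vectorized scoring
    mus = np.stack([r.mu for r in ensemble])             # (B, p)
    invs = np.stack([r.cov_inv for r in ensemble])       # (B, p, p)
    for i, sid in enumerate(subject_ids):
        d = residuals[i][None, :] - mus                  # (B, p)
        q = np.einsum("bi,bij,bj->b", d, invs, d)
        dist = np.sqrt(np.maximum(q, 0.0))
        out.append(MGMVResult(subject_id=sid, distances=dist,
                              m_gmv=float(np.median(dist)), B=B, m=m,
                              seed=seed))
    return out
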