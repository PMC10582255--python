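"""Progression regression: M_GMV predicting motor change, with effect sizes.

Ordinary least squares of each outcome delta on baseline M_GMV, covaried
for age and sex; the M_GMV coefficient is reported with a t-based 95% CI,
adjusted R² and Cohen's f² = R²_adj / (1 - R²_adj).  Significance is
Bonferroni-controlled over the six outcome families (alpha = 0.05/6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RegressionResult", "fit_progression_model", "cohens_f2",
           "effect_size_label", "bonferroni_flags", "BONFERRONI_ALPHA_OUTCOMES"]

BONFERRONI_ALPHA_OUTCOMES = 0.05 / 6

#: conventional small / medium / large cut-offs for Cohen's f²
F2_THRESHOLDS = (0.02, 0.15, 0.35)


@dataclass
class RegressionResult:
    outcome: str
    beta: float                 # coefficient of m_gmv
    ci95: tuple[float, float]
    r2: float
    r2_adj: float
    p: float                    # two-tailed p of the m_gmv coefficient
    f2: float | None            # absent when r2_adj <= 0
    effect_label: str           # small / medium / large / none
    n: int

    def as_row(self) -> dict:
        return {"outcome": self.outcome, "beta": self.beta,
                "ci_low": self.ci95[0], "ci_high": self.ci95[1],
                "r2_adj": self.r2_adj, "p": self.p,
                "f2": np.nan if self.f2 is None else self.f2,
                "effect": self.effect_label, "n": self.n}


def cohens_f2(r2_adj: float) -> float | None:
    """f² = R²_adj / (1 - R²_adj); None (reported as a dash) for R²_adj < 0."""
    if r2_adj >= 1:
        raise ValueError("adjusted R-squared must be < 1")
    if r2_adj < 0:
        return None
    return r2_adj / (1.0 - r2_adj)


def effect_size_label(f2: float | None) -> str:
    if f2 is None:
        return "none"
    small, medium, large = F2_THRESHOLDS
    if f2 >= large:
        return "large"
    if f2 >= medium:
        return "medium"
    if f2 >= small:
        return "small"
    return "none"


def fit_progression_model(m_gmv: np.ndarray, age: np.ndarray,
                          sex: np.ndarray, delta: np.ndarray,
                          outcome: str = "total") -> RegressionResult:
    """OLS: delta ~ intercept + m_gmv + age + sex.

    Sex is encoded 0/1.  Classical (non-robust) standard errors; the
    reported CI/p concern the M_GMV coefficient.
    """
    m_gmv = np.asarray(m_gmv, dtype=float)
    X = np.column_stack([m_gmv, np.asarray(age, dtype=float),
                         np.asarray(sex, dtype=float)])
    y = np.asarray(delta, dtype=float)
    n = len(y)
    if n <= 4:
        raise ValueError("need n > 4 for three predictors plus intercept")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in regression inputs")
    if np.ptp(y) == 0:
        # constant outcome: nothing to model, report a null result
        return RegressionResult(outcome=outcome, beta=0.0, ci95=(0.0, 0.0),
                                r2=0.0, r2_adj=0.0, p=1.0, f2=None,
                                effect_label="none", n=n)
    Xc = sm.add_constant(X, has_constant="add")
    cond = np.linalg.cond(Xc)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError(f"collinear design (condition number {cond:.3e})")
    fit = sm.OLS(y, Xc).fit()
    beta = float(fit.params[1])
    ci = fit.conf_int(alpha=0.05)
    r2_adj = float(fit.rsquared_adj)
    # a numerically perfect fit would push f2 out of its domain
    f2 = float("inf") if r2_adj >= 1 - 1e-12 else cohens_f2(r2_adj)
    return RegressionResult(
        outcome=outcome, beta=beta,
        ci95=(float(ci[1][0]), float(ci[1][1])),
        r2=float(fit.rsquared), r2_adj=r2_adj,
        p=float(fit.pvalues[1]), f2=f2,
        effect_label=effect_size_label(f2), n=n)


def bonferroni_flags(pvalues: list[float] | np.ndarray,
                     alpha: float = 0.05) -> np.ndarray:
    """Strict-inequality Bonferroni significance over the outcome family."""
    p = np.asarray(pvalues, dtype=float)
    return p < alpha / len(p)


def progression_table(results: list[RegressionResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.as_row() for r in results])
    df["significant"] = bonferroni_flags(df["p"].to_numpy())
    return df
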