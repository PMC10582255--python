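"""Empirical-Bayes location-scale site harmonization (ComBat model).

Per ROI j and subject i on site s the model is

    y_ijs = alpha_j + x_i' beta_j + gamma_js + delta_js * eps_ijs

where (diagnosis, age, sex) form the preserved biological covariates x,
gamma/delta are additive and multiplicative site effects, and eps is
unit-variance noise.  Raw per-site location/scale estimates are shrunk
toward parametric empirical-Bayes priors — normal for location,
inverse-gamma for scale, hyperparameters by method of moments — via the
standard conditional-posterior fixed point.  Harmonized data subtract the
shrunken site effects and reinsert the covariate-explained structure
unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["HarmonizationModel", "fit_combat", "apply_combat"]


@dataclass
class HarmonizationModel:
    site_ids: list[str]                    # fit-time site order
    n_per_site: np.ndarray                 # (S,)
    beta_hat: np.ndarray                   # (1 + n_cov, p): intercept + covariates
    grand_mean: np.ndarray                 # (p,)
    pooled_var: np.ndarray                 # (p,)
    gamma_star: np.ndarray                 # (S, p) EB-shrunken locations
    delta_star: np.ndarray                 # (S, p) EB-shrunken scales (variance)
    gamma_bar: np.ndarray = field(default_factory=lambda: np.empty(0))
    t2: np.ndarray = field(default_factory=lambda: np.empty(0))
    a_prior: np.ndarray = field(default_factory=lambda: np.empty(0))
    b_prior: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_json(self, path: str | Path) -> None:
        obj = {
            "site_ids": self.site_ids,
            "n_per_site": self.n_per_site.tolist(),
            "beta_hat": self.beta_hat.tolist(),
            "grand_mean": self.grand_mean.tolist(),
            "pooled_var": self.pooled_var.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "HarmonizationModel":
        obj = json.loads(Path(path).read_text())
        return cls(site_ids=obj["site_ids"],
                   n_per_site=np.asarray(obj["n_per_site"]),
                   beta_hat=np.asarray(obj["beta_hat"]),
                   grand_mean=np.asarray(obj["grand_mean"]),
                   pooled_var=np.asarray(obj["pooled_var"]),
                   gamma_star=np.asarray(obj["gamma_star"]),
                   delta_star=np.asarray(obj["delta_star"]))


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum_sq, n, a, b):
    return (0.5 * sum_sq + b) / (n / 2.0 + a - 1.0)


def _it_sol(s_data, g_hat, d_hat, g_bar, t2, a, b, conv=1e-6, max_iter=1000):
    """Empirical-Bayes fixed point for one site (classic formulation)."""
    n = s_data.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((s_data - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(np.max(np.abs(g_new - g_old) / np.abs(g_old + 1e-300)),
                     np.max(np.abs(d_new - d_old) / np.abs(d_old)))
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def _aprior(d_hat):
    m, s2 = d_hat.mean(), d_hat.var(ddof=1)
    return (2.0 * s2 + m ** 2) / s2


def _bprior(d_hat):
    m, s2 = d_hat.mean(), d_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def fit_combat(data: np.ndarray, site: np.ndarray,
               covariates: np.ndarray | None = None,
               conv: float = 1e-6, max_iter: int = 1000,
               ) -> HarmonizationModel:
    """Fit the EB location-scale model.

    Parameters
    ----------
    data : (n, p) array of GMV_N values (subjects x ROIs).
    site : (n,) array of site labels.
    covariates : (n, k) design of biological covariates to preserve
        (diagnosis, age, sex), without intercept; may be None.
    """
    data = np.asarray(data, dtype=float)
    site = np.asarray(site)
    n, p = data.shape
    site_ids = sorted(set(site.tolist()))
    S = len(site_ids)
    idx = {s: np.flatnonzero(site == s) for s in site_ids}
    n_per_site = np.array([len(idx[s]) for s in site_ids])
    if np.any(n_per_site < 2):
        small = site_ids[int(np.argmin(n_per_site))]
        raise ValueError(f"site {small!r} has < 2 subjects; "
                         "scale effect not estimable")

    # design: site one-hot (no intercept) followed by covariates
    batch = np.zeros((n, S))
    for j, s in enumerate(site_ids):
        batch[idx[s], j] = 1.0
    X = batch if covariates is None else np.column_stack(
        [batch, np.asarray(covariates, dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates/sites)")

    B_hat, *_ = np.linalg.lstsq(X, data, rcond=None)     # (S + k, p)
    grand_mean = (n_per_site / n) @ B_hat[:S]            # (p,)
    resid = data - X @ B_hat
    pooled_var = (resid ** 2).mean(axis=0)               # (p,)

    stand_mean = np.tile(grand_mean, (n, 1))
    if X.shape[1] > S:
        stand_mean = stand_mean + X[:, S:] @ B_hat[S:]
    s_data = (data - stand_mean) / np.sqrt(pooled_var)[None, :]

    gamma_hat = np.stack([s_data[idx[s]].mean(axis=0) for s in site_ids])
    delta_hat = np.stack([s_data[idx[s]].var(axis=0, ddof=1)
                          for s in site_ids])

    gamma_bar = gamma_hat.mean(axis=1)                   # (S,)
    t2 = gamma_hat.var(axis=1, ddof=1)                   # (S,)
    a_prior = np.array([_aprior(delta_hat[j]) for j in range(S)])
    b_prior = np.array([_bprior(delta_hat[j]) for j in range(S)])

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    if S == 1:
        # a single scanner leaves nothing to correct: exact no-op model
        gamma_star[:] = 0.0
        delta_star[:] = 1.0
        return HarmonizationModel(
            site_ids=site_ids, n_per_site=n_per_site,
            beta_hat=np.vstack([grand_mean[None, :], B_hat[S:]]),
            grand_mean=grand_mean, pooled_var=pooled_var,
            gamma_star=gamma_star, delta_star=delta_star,
            gamma_bar=gamma_bar, t2=t2, a_prior=a_prior, b_prior=b_prior)
    for j, s in enumerate(site_ids):
        g, d = _it_sol(s_data[idx[s]], gamma_hat[j], delta_hat[j],
                       gamma_bar[j], t2[j], a_prior[j], b_prior[j],
                       conv=conv, max_iter=max_iter)
        gamma_star[j], delta_star[j] = g, d

    # intercept-style representation: beta_hat holds grand mean + covariates
    k = X.shape[1] - S
    beta_hat = np.vstack([grand_mean[None, :],
                          B_hat[S:] if k else np.empty((0, p))])
    return HarmonizationModel(
        site_ids=site_ids, n_per_site=n_per_site, beta_hat=beta_hat,
        grand_mean=grand_mean, pooled_var=pooled_var,
        gamma_star=gamma_star, delta_star=delta_star,
        gamma_bar=gamma_bar, t2=t2, a_prior=a_prior, b_prior=b_prior)


def apply_combat(model: HarmonizationModel, data: np.ndarray,
                 site: np.ndarray,
                 covariates: np.ndarray | None = None) -> np.ndarray:
    """Remove fitted site effects; covariate structure passes through.

    Every site label must have been seen during fitting (no transductive
    extension to new scanners).
    """
    data = np.asarray(data, dtype=float)
    site = np.asarray(site)
    unseen = set(site.tolist()) - set(model.site_ids)
    if unseen:
        raise ValueError(f"unseen site label(s) {sorted(unseen)!r}")
    n, p = data.shape
    stand_mean = np.tile(model.grand_mean, (n, 1))
    if covariates is not None and model.beta_hat.shape[0] > 1:
        stand_mean = stand_mean + np.asarray(
            covariates, dtype=float) @ model.beta_hat[1:]
    s_data = (data - stand_mean) / np.sqrt(model.pooled_var)[None, :]
    out = np.empty_like(s_data)
    for j, s in enumerate(model.site_ids):
        rows = np.flatnonzero(site == s)
        if rows.size == 0:
            continue
        out[rows] = ((s_data[rows] - model.gamma_star[j][None, :])
                     / np.sqrt(model.delta_star[j])[None, :])
    return out * np.sqrt(model.pooled_var)[None, :] + stand_mean
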