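"""Multiple imputation by chained equations (MICE) and Rubin's-rules pooling.

Missing predictors are imputed on the raw measurement scale (SpO2, MUAC,
WAZ, Blantyre coma score, AVPU, wheeze, HIV status); model indicator
categories are derived only after imputation so the published threshold
definitions stay exact. Each incomplete field is visited in ascending order
of missingness and imputed conditional on the other fields, the outcome and
the complete demographics, cycling for a fixed number of iterations and
repeated m times.

Per-field methods:

* continuous fields — predictive mean matching (PMM, k = 5 donors) with a
  proper Bayesian parameter draw (residual variance from a scaled
  inverse-chi-square draw, coefficients from their normal posterior);
* binary fields — logistic regression with a normal-approximation
  coefficient draw, then Bernoulli draws;
* the AVPU category — multinomial logistic draws from plug-in class
  probabilities.

Pooling follows Rubin's rules: point estimate Q-bar = mean of the m
per-imputation estimates; within variance W = mean of their variances;
between variance B = sample variance of the estimates; total
T = W + (1 + 1/m) B; degrees of freedom (m-1)(1 + W/((1+1/m)B))^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientRecord, frame_to_records, records_to_frame
from .errors import AllMissingFieldError, NonConvergenceError
from .metrics import fit_logistic

__all__ = [
    "ImputationConfig",
    "PooledEstimate",
    "DEFAULT_METHODS",
    "mice_impute",
    "mice_impute_frame",
    "rubin_pool",
    "imputation_diagnostics",
]

DEFAULT_METHODS = {
    "spo2_pct": "pmm",
    "muac_mm": "pmm",
    "waz": "pmm",
    "bcs": "pmm",
    "wheeze": "logistic",
    "hiv_positive": "logistic",
    "avpu": "multinomial",
}

_AVPU_CODES = {"A": 0.0, "V": 1.0, "P": 2.0, "U": 3.0}
_AVPU_LEVELS = ["A", "V", "P", "U"]


@dataclass
class ImputationConfig:
    """m completed datasets, n_iter chained-equation sweeps each."""

    m: int = 50
    n_iter: int = 100
    seed: int = 0
    methods: dict = dc_field(default_factory=lambda: dict(DEFAULT_METHODS))
    include_outcome: bool = True  # standard MI practice for validation studies

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class PooledEstimate:
    """Rubin-combined estimate: T = W + (1 + 1/m) B."""

    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci: tuple[float, float]


# ---------------------------------------------------------------------------
# Numeric working representation
# ---------------------------------------------------------------------------

def _to_numeric(df: pd.DataFrame, fields: Sequence[str]) -> pd.DataFrame:
    num = pd.DataFrame(index=df.index)
    for f in fields:
        if f == "avpu":
            num[f] = df[f].map(_AVPU_CODES)
        elif f in ("wheeze", "hiv_positive"):
            num[f] = df[f].map({"yes": 1.0, "no": 0.0})
        else:
            num[f] = df[f].astype(float)
    return num


def _from_numeric(num: pd.DataFrame, template: pd.DataFrame) -> pd.DataFrame:
    out = template.copy()
    for f in num.columns:
        if f == "avpu":
            out[f] = num[f].map(dict(enumerate(_AVPU_LEVELS)))
        elif f in ("wheeze", "hiv_positive"):
            out[f] = num[f].map({1.0: "yes", 0.0: "no"})
        else:
            out[f] = num[f]
    return out


def _predictor_matrix(num: pd.DataFrame, df: pd.DataFrame, target: str,
                      fields: Sequence[str], include_outcome: bool) -> np.ndarray:
    cols = [np.ones(len(df))]
    cols.append(df["age_months"].to_numpy(float))
    cols.append((df["sex"] == "female").to_numpy(float))
    if include_outcome:
        cols.append((df["outcome"] == "died").to_numpy(float))
    for f in fields:
        if f == target:
            continue
        v = num[f].to_numpy(float)
        if f == "avpu":  # dummies, not ordinal, when used as a predictor
            for level in (1.0, 2.0, 3.0):
                cols.append((v == level).astype(float))
        else:
            cols.append(v)
    return np.column_stack(cols)


def _drop_collinear(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Keep a maximal linearly independent column subset."""
    _, rr = np.linalg.qr(X)
    diag = np.abs(np.diag(rr))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if np.all(diag > tol):
        return X, np.arange(X.shape[1])
    keep: list[int] = []
    for j in range(X.shape[1]):
        if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep) + 1:
            keep.append(j)
    idx = np.array(keep)
    return X[:, idx], idx


# ---------------------------------------------------------------------------
# Per-field samplers
# ---------------------------------------------------------------------------

def _impute_pmm(X, y, obs, mis, rng, k=5):
    Xo, keep = _drop_collinear(X[obs])
    Xm = X[mis][:, keep]
    yo = y[obs]
    n, p = Xo.shape
    beta_hat, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / stats.chi2.rvs(dof, random_state=rng)
    XtX_inv = np.linalg.pinv(Xo.T @ Xo)
    chol = np.linalg.cholesky(XtX_inv + 1e-12 * np.eye(p))
    beta_draw = beta_hat + np.sqrt(sigma2) * chol @ rng.standard_normal(p)
    pred_obs = Xo @ beta_hat
    pred_mis = Xm @ beta_draw
    # tiny jitter breaks prediction ties so near-constant prediction models
    # draw donors from the whole tied pool, not a fixed sort-order window
    spread = np.ptp(pred_obs) or 1.0
    pred_obs = pred_obs + rng.normal(0, 1e-9 * spread, len(pred_obs))
    pred_mis = pred_mis + rng.normal(0, 1e-9 * spread, len(pred_mis))
    order = np.argsort(pred_obs)
    sorted_pred = pred_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    lo = np.clip(pos - k // 2 - 1, 0, max(n - k, 0))
    offs = rng.integers(0, min(k, n), size=len(pred_mis))
    donor_idx = order[np.clip(lo + offs, 0, n - 1)]
    return yo[donor_idx]


def _impute_logistic(X, y, obs, mis, rng):
    Xo, keep = _drop_collinear(X[obs])
    Xm = X[mis][:, keep]
    yo = y[obs]
    try:
        fit = fit_logistic(Xo, yo, score_tol=1e-6, dev_tol=1e-8)
        chol = np.linalg.cholesky(fit.cov + 1e-12 * np.eye(len(fit.coefficients)))
        beta = fit.coefficients + chol @ rng.standard_normal(len(fit.coefficients))
        p = 1.0 / (1.0 + np.exp(-(Xm @ beta)))
    except NonConvergenceError:
        p = np.full(len(Xm), yo.mean())  # separation: fall back to marginal
    return (rng.random(len(Xm)) < p).astype(float)


def _impute_multinomial(X, y, obs, mis, rng):
    from sklearn.linear_model import LogisticRegression

    yo = y[obs].astype(int)
    classes = np.unique(yo)
    if classes.size == 1:
        return np.full(int(np.sum(mis)), float(classes[0]))
    Z = X[:, 1:]  # sklearn adds its own intercept
    mu, sd = Z[obs].mean(axis=0), Z[obs].std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Z - mu) / sd
    clf = LogisticRegression(max_iter=1000)
    clf.fit(Z[obs], yo)
    proba = clf.predict_proba(Z[mis])
    cum = np.cumsum(proba, axis=1)
    u = rng.random(len(cum))
    picks = (u[:, None] < cum).argmax(axis=1)
    return clf.classes_[picks].astype(float)


# ---------------------------------------------------------------------------
# Chained equations
# ---------------------------------------------------------------------------

def mice_impute_frame(df: pd.DataFrame, fields: Sequence[str],
                      config: ImputationConfig) -> list[pd.DataFrame]:
    """MICE on a cohort frame; returns m completed copies.

    Observed cells are never altered. The visit order is ascending
    missingness. Fields with no missing values are carried through
    untouched (and still serve as predictors).
    """
    methods = {**DEFAULT_METHODS, **config.methods}
    num_full = _to_numeric(df, fields)
    miss_mask = {f: num_full[f].isna().to_numpy() for f in fields}
    for f in fields:
        if miss_mask[f].all():
            raise AllMissingFieldError(f"field {f!r} has no observed values")
    rates = {f: miss_mask[f].mean() for f in fields}
    visit = sorted([f for f in fields if miss_mask[f].any()], key=lambda f: rates[f])

    seeds = np.random.SeedSequence(config.seed).spawn(config.m)
    completed = []
    for j in range(config.m):
        rng = np.random.default_rng(seeds[j])
        num = num_full.copy()
        # initial fill: random draws from the observed values of each field
        for f in visit:
            obs_vals = num_full[f].dropna().to_numpy()
            m_idx = miss_mask[f]
            num.loc[m_idx, f] = rng.choice(obs_vals, size=m_idx.sum(), replace=True)
        chain_means = []
        for _it in range(config.n_iter):
            for f in visit:
                m_idx = miss_mask[f]
                o_idx = ~m_idx
                X = _predictor_matrix(num, df, f, fields, config.include_outcome)
                y = num[f].to_numpy(float)
                method = methods.get(f, "pmm")
                if method == "pmm":
                    drawn = _impute_pmm(X, y, o_idx, m_idx, rng)
                elif method == "logistic":
                    drawn = _impute_logistic(X, y, o_idx, m_idx, rng)
                elif method == "multinomial":
                    drawn = _impute_multinomial(X, y, o_idx, m_idx, rng)
                else:
                    raise ValueError(f"unknown method {method!r} for field {f!r}")
                num.loc[m_idx, f] = drawn
            chain_means.append([num.loc[miss_mask[f], f].mean() for f in visit])
        if config.n_iter >= 4 and visit:
            # crude chain diagnostic: warn when a field's imputed mean still
            # shifts by a fifth of its observed spread between the first and
            # second half of the chain. Halves are compared (not single
            # sweeps) because each sweep's parameter draw is a common shock
            # to every imputed cell, which averaging across sweeps damps.
            cm = np.asarray(chain_means)[1:]  # first sweep is burn-in
            half = len(cm) // 2
            drift = np.abs(cm[half:].mean(axis=0) - cm[:half].mean(axis=0))
            scale = np.array([float(num_full[f].std()) for f in visit])
            scale[~np.isfinite(scale) | (scale == 0)] = 1.0
            if np.any(drift > 0.2 * scale):
                warnings.warn(
                    f"imputation chains may not have converged after "
                    f"{config.n_iter} iterations", RuntimeWarning
                )
        completed.append(_from_numeric(num, df))
    return completed


def mice_impute(records: Sequence[PatientRecord], fields: Sequence[str],
                config: ImputationConfig) -> list[list[PatientRecord]]:
    """MICE over patient records; returns m completed record lists."""
    df = records_to_frame(list(records))
    frames = mice_impute_frame(df, fields, config)
    return [frame_to_records(fr) for fr in frames]


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

def rubin_pool(estimates, variances, m: int | None = None,
               ci_level: float = 0.95) -> PooledEstimate:
    """Combine m per-imputation estimates and variances.

    Q-bar = mean(estimates); W = mean(variances); B = sample variance of
    the estimates; T = W + (1 + 1/m) B; df = (m-1)(1 + W/((1+1/m)B))^2
    (infinite when B = 0); CI = Q-bar +/- t(df) sqrt(T).
    """
    q = np.asarray(estimates, float)
    u = np.asarray(variances, float)
    if q.shape != u.shape:
        raise ValueError("estimates and variances must have equal length")
    if np.any(u < 0):
        raise ValueError("variances must be nonnegative")
    m = len(q) if m is None else m
    if m != len(q):
        raise ValueError("m does not match the number of estimates")
    qbar = float(q.mean())
    W = float(u.mean())
    # identical estimates have exactly zero between-imputation variance;
    # np.var would return summation noise ~1e-32
    B = float(q.var(ddof=1)) if (m > 1 and np.ptp(q) > 0) else 0.0
    T = W + (1 + 1 / m) * B
    if B > 0:
        df = (m - 1) * (1 + W / ((1 + 1 / m) * B)) ** 2
        tq = stats.t.ppf(1 - (1 - ci_level) / 2, df)
    else:
        df = np.inf
        tq = stats.norm.ppf(1 - (1 - ci_level) / 2)
    half = tq * np.sqrt(T)
    return PooledEstimate(qbar, W, B, T, float(df), (qbar - half, qbar + half))


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def imputation_diagnostics(observed, imputed_per_imputation) -> dict:
    """Observed-vs-imputed distribution summary for one field.

    Returns the 5/25/50/75/95 percentiles of the observed values and of
    each imputation's imputed values, plus a flag raised when any
    imputation's median falls outside the observed 5-95% range (the
    standard plausibility check that replaces eyeballing density plots).
    """
    obs = np.asarray(observed, float)
    obs = obs[~np.isnan(obs)]
    if obs.size == 0:
        raise AllMissingFieldError("no observed values to compare against")
    qs = (5, 25, 50, 75, 95)
    obs_q = {f"p{p}": float(v) for p, v in zip(qs, np.percentile(obs, qs))}
    per_imp = []
    flag = False
    for imp in imputed_per_imputation:
        imp = np.asarray(imp, float)
        if imp.size == 0:
            continue
        iq = {f"p{p}": float(v) for p, v in zip(qs, np.percentile(imp, qs))}
        per_imp.append(iq)
        if not (obs_q["p5"] <= iq["p50"] <= obs_q["p95"]):
            flag = True
    return {"observed": obs_q, "imputed": per_imp, "flag": flag}
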