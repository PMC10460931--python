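"""Discrimination and calibration metrics for predicted mortality risks.

Discrimination is the concordance probability (c-statistic / AUC): the
probability that a randomly chosen death received a higher predicted risk
than a randomly chosen survivor, with ties counted 1/2. It is computed from
midranks in O(n log n) and banded with the conventional cutoffs
(>=0.90 excellent, 0.80-0.89 good, 0.70-0.79 fair, <0.70 poor).

Calibration is assessed on the log-odds scale. With lp the model's linear
predictor:

* calibration-in-the-large (intercept): fit logit P(y=1) = a + lp with the
  slope fixed at 1 (lp enters as an offset). a > 0 means risks are
  underestimated on average, a < 0 overestimated.
* calibration slope: fit logit P(y=1) = a + b*lp with both free. b < 1
  means predictions are too extreme, b > 1 too moderate.
* flexible curve: logit P(y=1) = f(logit(risk)) with f a restricted cubic
  spline, evaluated on a grid over the observed risk range.

All three fits share one iteratively reweighted least squares engine
(:func:`fit_logistic`) supporting an offset term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit
from scipy.stats import rankdata

from .errors import (
    DegenerateOutcomeError,
    InsufficientDataError,
    NonConvergenceError,
    RankDeficiencyError,
)

__all__ = [
    "ValidationResult",
    "LogisticFit",
    "c_statistic",
    "classify_auc",
    "calibration_intercept",
    "calibration_slope",
    "flexible_calibration_curve",
    "fit_logistic",
    "rcs_basis",
    "rcs_knots",
]

_RISK_EPS = 1e-12  # clip before logit so degenerate 0/1 risks stay finite


@dataclass
class ValidationResult:
    """Discrimination and calibration of one model on one cohort."""

    auc: float
    auc_ci: tuple[float, float]
    auc_band: str
    cal_slope: float
    cal_slope_ci: tuple[float, float]
    cal_intercept: float
    cal_intercept_ci: tuple[float, float]
    n: int
    n_events: int
    curve: list[tuple[float, float]]


@dataclass
class LogisticFit:
    coefficients: np.ndarray
    converged: bool
    n_iter: int
    cov: np.ndarray | None = None


def _check_binary(outcomes: np.ndarray) -> None:
    u = np.unique(outcomes)
    if not np.all(np.isin(u, (0, 1))):
        raise ValueError("outcomes must be coded 0/1")
    if u.size < 2:
        raise DegenerateOutcomeError("need both events and non-events")


def c_statistic(risks, outcomes) -> float:
    """Concordance probability via midranks: (concordant + ties/2) / (n1*n0)."""
    risks = np.asarray(risks, float)
    outcomes = np.asarray(outcomes)
    if risks.shape != outcomes.shape:
        raise ValueError("risks and outcomes must have equal length")
    _check_binary(outcomes)
    y = outcomes.astype(bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = rankdata(risks)  # midranks
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def classify_auc(auc: float) -> str:
    """Band an AUC: >=0.90 excellent, >=0.80 good, >=0.70 fair, else poor."""
    if not (0 <= auc <= 1):
        raise ValueError(f"AUC {auc} outside [0, 1]")
    if auc >= 0.90:
        return "excellent"
    if auc >= 0.80:
        return "good"
    if auc >= 0.70:
        return "fair"
    return "poor"


def fit_logistic(design, outcomes, offset=None, max_iter=100,
                 score_tol=1e-8, dev_tol=1e-10) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton/IRLS with an offset.

    Converges when the maximum absolute score-equation residual falls below
    ``score_tol`` or the relative deviance change falls below ``dev_tol``.
    Complete separation shows up as diverging coefficients and is reported
    as non-convergence with the iteration trace attached.
    """
    X = np.asarray(design, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcomes, float)
    off = np.zeros(len(y)) if offset is None else np.asarray(offset, float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise RankDeficiencyError(f"design matrix rank < {p}")

    def deviance(b):
        mu = expit(X @ b + off)
        with np.errstate(divide="ignore", invalid="ignore"):
            return -2 * float(
                np.sum(np.where(y == 1, np.log(np.clip(mu, 1e-300, None)),
                                np.log(np.clip(1 - mu, 1e-300, None))))
            )

    beta = np.zeros(p)
    dev_prev = deviance(beta)
    trace = []
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta + off)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        trace.append((it, dev_prev, float(np.max(np.abs(score)))))
        if np.max(np.abs(score)) < score_tol:
            if dev_prev < 1e-6:  # perfect fit of binary outcomes = separation
                raise NonConvergenceError(
                    "deviance vanished: outcomes are perfectly separated", trace
                )
            return LogisticFit(beta, True, it, np.linalg.inv(info))
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise NonConvergenceError(f"singular information matrix at iter {it}",
                                      trace) from exc
        # damped Newton: halve the step while the deviance worsens
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            dev = deviance(cand)
            if dev <= dev_prev + 1e-12:
                break
            lam /= 2
        beta = cand
        # separation drives the fitted log-odds to +/- infinity even though
        # collinear designs can have legitimately large coefficients
        if np.max(np.abs(X @ beta + off)) > 100:
            raise NonConvergenceError(
                "fitted log-odds diverging (complete or quasi-complete separation)",
                trace,
            )
        if abs(dev_prev - dev) < dev_tol * max(abs(dev), 1.0):
            if dev < 1e-6:
                raise NonConvergenceError(
                    "deviance vanished: outcomes are perfectly separated", trace
                )
            mu = expit(X @ beta + off)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            info = (X * w[:, None]).T @ X
            return LogisticFit(beta, True, it, np.linalg.inv(info))
        dev_prev = dev
    raise NonConvergenceError(f"no convergence in {max_iter} iterations", trace)


def calibration_intercept(lp, outcomes) -> float:
    """Calibration-in-the-large: intercept of logit P(y=1) = a + lp with the
    linear predictor as a fixed-slope offset."""
    lp = np.asarray(lp, float)
    outcomes = np.asarray(outcomes)
    _check_binary(outcomes)
    fit = fit_logistic(np.ones((len(lp), 1)), outcomes, offset=lp)
    return float(fit.coefficients[0])


def calibration_slope(lp, outcomes) -> float:
    """Slope b of logit P(y=1) = a + b*lp, intercept free."""
    lp = np.asarray(lp, float)
    outcomes = np.asarray(outcomes)
    _check_binary(outcomes)
    if np.ptp(lp) == 0:
        raise InsufficientDataError("linear predictor is constant; slope undefined")
    X = np.column_stack([np.ones_like(lp), lp])
    fit = fit_logistic(X, outcomes)
    return float(fit.coefficients[1])


def rcs_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    """Knots at the conventional quantiles: 5/27.5/50/72.5/95 for five
    knots, 10/50/90 for three."""
    if n_knots == 5:
        q = (5, 27.5, 50, 72.5, 95)
    elif n_knots == 3:
        q = (10, 50, 90)
    else:
        raise ValueError("supported knot counts: 3, 5")
    knots = np.percentile(x, q)
    if np.unique(knots).size < len(knots):
        raise InsufficientDataError("tied knots; too little spread in risks")
    return knots


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline basis, linear beyond the boundary
    knots: columns [x, s_1(x), ..., s_{k-2}(x)] with the usual truncated
    power construction scaled by (t_k - t_1)^2."""
    x = np.asarray(x, float)
    t = np.asarray(knots, float)
    k = len(t)
    scale = (t[-1] - t[0]) ** 2
    cols = [x]
    def pos3(v):
        return np.clip(v, 0, None) ** 3
    for j in range(k - 2):
        term = (
            pos3(x - t[j])
            - pos3(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + pos3(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        )
        cols.append(term / scale)
    return np.column_stack(cols)


def flexible_calibration_curve(risks, outcomes, n_points: int = 50,
                               grid_risks=None) -> list[tuple[float, float]]:
    """Smooth observed-vs-predicted curve via a restricted-cubic-spline
    recalibration of logit(risk).

    Five knots by default, dropping to three when there are fewer than 100
    events. Returns ``n_points`` (predicted, observed) pairs over the
    observed risk range, or over ``grid_risks`` when given (used to pool
    curves across imputations on a common grid).
    """
    risks = np.asarray(risks, float)
    outcomes = np.asarray(outcomes)
    if len(risks) < 50:
        raise InsufficientDataError("need at least 50 observations for a curve")
    _check_binary(outcomes)
    if np.ptp(risks) == 0:
        raise InsufficientDataError("constant risks; curve undefined")
    x = logit(np.clip(risks, _RISK_EPS, 1 - _RISK_EPS))
    n_events = int(np.asarray(outcomes).sum())
    knots = rcs_knots(x, 5 if n_events >= 100 else 3)
    B = rcs_basis(x, knots)
    # standardize the basis for numerical stability; undo on the grid
    mu, sd = B.mean(axis=0), B.std(axis=0)
    sd[sd == 0] = 1.0
    X = np.column_stack([np.ones_like(x), (B - mu) / sd])
    fit = fit_logistic(X, outcomes)
    if grid_risks is None:
        grid_x = np.linspace(x.min(), x.max(), n_points)
    else:
        grid_x = logit(np.clip(np.asarray(grid_risks, float), _RISK_EPS, 1 - _RISK_EPS))
    Bg = (rcs_basis(grid_x, knots) - mu) / sd
    Xg = np.column_stack([np.ones_like(grid_x), Bg])
    obs = expit(Xg @ fit.coefficients)
    pred = expit(grid_x)
    return list(zip(pred.tolist(), obs.tolist()))
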