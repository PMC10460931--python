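"""Concordance, AUC bands, IRLS engine, calibration fits, spline curve."""

import numpy as np
import pytest
from scipy.special import expit, logit

from pmvalidate import (
    DegenerateOutcomeError,
    InsufficientDataError,
    NonConvergenceError,
    RankDeficiencyError,
    c_statistic,
    calibration_intercept,
    calibration_slope,
    classify_auc,
    fit_logistic,
    flexible_calibration_curve,
)


def brute_force_concordance(risks, outcomes):
    """Independent oracle: enumerate every (event, non-event) pair."""
    risks = np.asarray(risks, float)
    y = np.asarray(outcomes).astype(bool)
    ev, nev = risks[y], risks[~y]
    wins = (ev[:, None] > nev[None, :]).sum()
    ties = (ev[:, None] == nev[None, :]).sum()
    return (wins + 0.5 * ties) / (len(ev) * len(nev))


class TestCStatistic:
    def test_perfect_separation(self):
        assert c_statistic([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied(self):
        assert c_statistic([0.3] * 6, [1, 0, 1, 0, 0, 0]) == 0.5

    def test_hand_enumerated_pairs(self):
        assert c_statistic([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) == 0.75

    def test_degenerate_outcomes_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            c_statistic([0.1, 0.2], [1, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            c_statistic([0.1, 0.2, 0.3], [1, 0])

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = rng.integers(10, 200)
            risks = rng.choice([0.1, 0.2, 0.5, 0.7, 0.9], n)  # force ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            assert c_statistic(risks, y) == brute_force_concordance(risks, y)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        risks = rng.random(500)
        y = rng.integers(0, 2, 500)
        lp = logit(risks)
        assert c_statistic(risks, y) == pytest.approx(c_statistic(lp, y), abs=1e-12)

    def test_complement_symmetry(self):
        rng = np.random.default_rng(9)
        risks = rng.random(300)
        y = rng.integers(0, 2, 300)
        assert c_statistic(risks, y) + c_statistic(risks, 1 - y) == pytest.approx(1.0)


class TestClassifyAuc:
    @pytest.mark.parametrize(
        "auc, band",
        [(0.95, "excellent"), (0.90, "excellent"), (0.85, "good"), (0.80, "good"),
         (0.77, "fair"), (0.70, "fair"), (0.69, "poor"), (0.5, "poor")],
    )
    def test_bands(self, auc, band):
        assert classify_auc(auc) == band

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_auc(1.2)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(3), np.zeros(7)]
        fit = fit_logistic(np.ones((10, 1)), y)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(logit(0.3), abs=1e-10)

    def test_two_group_closed_form(self):
        # groups of 100: 30% vs 60% events; saturated model has exact MLE
        x = np.r_[np.zeros(100), np.ones(100)]
        y = np.r_[np.ones(30), np.zeros(70), np.ones(60), np.zeros(40)]
        fit = fit_logistic(np.column_stack([np.ones(200), x]), y)
        assert fit.coefficients[0] == pytest.approx(logit(0.3), abs=1e-8)
        assert fit.coefficients[1] == pytest.approx(logit(0.6) - logit(0.3), abs=1e-8)

    def test_offset_shifts_intercept(self):
        rng = np.random.default_rng(3)
        off = rng.normal(-1, 1, 20000)
        y = (rng.random(20000) < expit(off + 0.4)).astype(float)
        fit = fit_logistic(np.ones((20000, 1)), y, offset=off)
        assert fit.coefficients[0] == pytest.approx(0.4, abs=0.06)

    def test_separation_raises_with_trace(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(NonConvergenceError) as exc:
            fit_logistic(np.column_stack([np.ones(20), x]), x.copy())
        assert exc.value.trace  # iteration trace attached

    def test_rank_deficiency(self):
        X = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(RankDeficiencyError):
            fit_logistic(X, np.r_[np.ones(15), np.zeros(15)])

    def test_matches_statsmodels_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        X = np.column_stack([np.ones(2000), rng.normal(size=2000), rng.random(2000)])
        off = rng.normal(0, 0.5, 2000)
        y = (rng.random(2000) < expit(X @ [-1.0, 0.8, -0.4] + off)).astype(float)
        ours = fit_logistic(X, y, offset=off)
        ref = sm.GLM(y, X, family=sm.families.Binomial(), offset=off).fit()
        np.testing.assert_allclose(ours.coefficients, ref.params, atol=1e-6)


class TestCalibration:
    def test_intercept_recovery(self):
        rng = np.random.default_rng(21)
        lp = rng.normal(-2.0, 1.0, 50_000)
        for delta in (0.0, 0.8, -0.5):
            y = (rng.random(50_000) < expit(lp + delta)).astype(int)
            assert calibration_intercept(lp, y) == pytest.approx(delta, abs=0.05)

    def test_slope_recovery(self):
        rng = np.random.default_rng(22)
        lp = rng.normal(-2.0, 1.0, 50_000)
        centered = lp - lp.mean()
        for gamma in (1.0, 0.5, 1.5):
            y = (rng.random(50_000) < expit(gamma * centered - 2.0)).astype(int)
            assert calibration_slope(lp, y) == pytest.approx(gamma, abs=0.05)

    def test_constant_lp_rejected(self):
        with pytest.raises(InsufficientDataError):
            calibration_slope(np.zeros(100), np.r_[np.ones(50), np.zeros(50)])

    def test_sign_semantics(self):
        # underestimation (true risk above predictions) gives intercept > 0
        rng = np.random.default_rng(23)
        lp = rng.normal(-3.0, 1.0, 50_000)
        y_hi = (rng.random(50_000) < expit(lp + 0.8)).astype(int)
        y_lo = (rng.random(50_000) < expit(lp - 0.8)).astype(int)
        assert calibration_intercept(lp, y_hi) > 0 > calibration_intercept(lp, y_lo)


class TestFlexibleCurve:
    def test_calibrated_curve_tracks_diagonal(self):
        rng = np.random.default_rng(31)
        lp = rng.normal(-2.0, 1.0, 50_000)
        y = (rng.random(50_000) < expit(lp)).astype(int)
        pts = np.array(flexible_calibration_curve(expit(lp), y, n_points=60))
        pred, obs = pts[:, 0], pts[:, 1]
        lo, hi = np.percentile(expit(lp), [5, 95])
        central = (pred >= lo) & (pred <= hi)
        assert np.all(np.abs(pred[central] - obs[central]) < 0.05)

    def test_underestimation_lifts_curve(self):
        rng = np.random.default_rng(32)
        lp = rng.normal(-2.0, 1.0, 50_000)
        y = (rng.random(50_000) < expit(lp + 0.8)).astype(int)
        pts = np.array(flexible_calibration_curve(expit(lp), y, n_points=40))
        lo, hi = np.percentile(expit(lp), [5, 95])
        central = (pts[:, 0] >= lo) & (pts[:, 0] <= hi)
        assert np.all(pts[central, 1] > pts[central, 0])

    def test_constant_risks_rejected(self):
        y = np.r_[np.ones(40), np.zeros(60)]
        with pytest.raises(InsufficientDataError):
            flexible_calibration_curve(np.full(100, 0.3), y)

    def test_too_few_observations_rejected(self):
        with pytest.raises(InsufficientDataError):
            flexible_calibration_curve([0.1, 0.9] * 10, [0, 1] * 10)

    def test_observed_values_are_probabilities(self):
        rng = np.random.default_rng(33)
        lp = rng.normal(-1.0, 2.0, 5_000)
        y = (rng.random(5_000) < expit(lp)).astype(int)
        pts = np.array(flexible_calibration_curve(expit(lp), y, n_points=30))
        assert np.all((0 <= pts[:, 1]) & (pts[:, 1] <= 1))
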