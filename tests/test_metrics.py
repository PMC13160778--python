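import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from rpntcp import (auc, bootstrap_auc_ci, brier, calibration_curve,
                    citl_and_slope, fit_stats, hosmer_lemeshow)


def brute_force_auc(pred, y):
    """Exhaustive concordant-pair counting (ties count 1/2)."""
    pos = pred[y == 1]
    neg = pred[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_constant_predictions_are_chance(self):
        assert auc([0.3] * 6, [1, 0, 1, 0, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        pred = np.round(rng.uniform(size=40), 2)  # rounding forces ties
        y = rng.integers(0, 2, 40)
        if y.sum() in (0, len(y)):
            y[0] = 1 - y[0]
        expected = brute_force_auc(pred, y)
        assert auc(pred, y) == pytest.approx(expected, abs=1e-12)
        assert auc(pred, y) == pytest.approx(roc_auc_score(y, pred), abs=1e-12)

    @given(shift=st.floats(-3, 3), scale=st.floats(0.1, 5))
    @settings(deadline=None, derandomize=True)
    def test_invariant_under_strictly_increasing_transforms(self, shift, scale):
        rng = np.random.default_rng(7)
        pred = rng.uniform(size=60)
        y = rng.integers(0, 2, 60)
        y[0], y[1] = 0, 1
        trans = 1 / (1 + np.exp(-(shift + scale * np.log(pred / (1 - pred)))))
        assert auc(trans, y) == auc(pred, y)


class TestBootstrapCI:
    def test_degenerate_perfect_data_gives_unit_interval(self):
        y = np.array([1, 1, 1, 0, 0, 0, 1, 0, 1, 0])
        lo, hi = bootstrap_auc_ci(y.astype(float), y, B=100, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        pred, y = rng.uniform(size=80), rng.integers(0, 2, 80)
        assert bootstrap_auc_ci(pred, y, B=200, seed=9) == \
            bootstrap_auc_ci(pred, y, B=200, seed=9)

    def test_interval_narrows_with_sample_size(self):
        rng = np.random.default_rng(5)
        widths = []
        for n in (100, 1600):
            x = rng.normal(size=n)
            y = (rng.uniform(size=n) < 1 / (1 + np.exp(-x))).astype(int)
            pred = 1 / (1 + np.exp(-x))
            lo, hi = bootstrap_auc_ci(pred, y, B=300, seed=11)
            widths.append(hi - lo)
        assert widths[1] < widths[0] / 2  # roughly 1/sqrt(n)


class TestBrier:
    def test_trivial_cases(self):
        y = np.array([1, 0, 1, 0])
        assert brier(y.astype(float), y) == 0.0
        assert brier([0.5] * 4, y) == 0.25

    def test_prevalence_constant_gives_binomial_variance(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        pi = y.mean()
        assert brier([pi] * len(y), y) == pytest.approx(pi * (1 - pi), abs=1e-12)


class TestFitStats:
    def test_null_model_has_zero_nagelkerke(self):
        y = np.array([1, 0, 1, 0, 0, 1, 0, 0])
        fs = fit_stats(np.full(len(y), y.mean()), y, k=1)
        assert fs.nagelkerke_r2 == pytest.approx(0.0, abs=1e-12)

    def test_aic_bic_identity(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        fs = fit_stats(rng.uniform(0.1, 0.9, 50), y, k=3)
        assert fs.aic - fs.bic == pytest.approx(2 * 3 - 3 * math.log(50), abs=1e-10)

    def test_hand_computed_toy(self):
        """Independent textbook computation on n=6."""
        y = np.array([1, 0, 1, 1, 0, 0])
        p = np.array([0.8, 0.3, 0.6, 0.9, 0.2, 0.4])
        ll = sum(math.log(pi) if yi else math.log(1 - pi) for yi, pi in zip(y, p))
        pi0 = 0.5
        ll0 = 6 * (pi0 * math.log(pi0) + (1 - pi0) * math.log(1 - pi0))
        r2_cs = 1 - math.exp(2 * (ll0 - ll) / 6)
        expected_nagelkerke = r2_cs / (1 - math.exp(2 * ll0 / 6))
        fs = fit_stats(p, y, k=2)
        assert fs.log_likelihood == pytest.approx(ll, abs=1e-10)
        assert fs.aic == pytest.approx(-2 * ll + 4, abs=1e-10)
        assert fs.bic == pytest.approx(-2 * ll + 2 * math.log(6), abs=1e-10)
        assert fs.nagelkerke_r2 == pytest.approx(expected_nagelkerke, abs=1e-10)


class TestCalibration:
    def test_self_fitted_predictions_are_perfectly_calibrated(self):
        rng = np.random.default_rng(21)
        import statsmodels.api as sm
        x = rng.normal(size=800)
        y = (rng.uniform(size=800) < 1 / (1 + np.exp(-(-1 + 0.8 * x)))).astype(float)
        fit = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        pred = fit.predict()
        cal = citl_and_slope(pred, y)
        assert cal.citl == pytest.approx(0.0, abs=1e-6)
        assert cal.slope == pytest.approx(1.0, abs=1e-6)

    def test_recovers_injected_logit_shift(self):
        rng = np.random.default_rng(22)
        n = 20000
        lp = rng.normal(-1.0, 1.0, n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-lp))).astype(float)
        delta = 0.7
        shifted = 1 / (1 + np.exp(-(lp + delta)))
        cal = citl_and_slope(shifted, y)
        # CITL should undo the shift; 3 Monte-Carlo SEs of tolerance
        assert cal.citl == pytest.approx(-delta, abs=3 * 0.05)
        assert cal.slope == pytest.approx(1.0, abs=3 * 0.05)

    def test_slope_recovers_generating_coefficient(self):
        rng = np.random.default_rng(23)
        n = 50000
        lp = rng.normal(0.0, 1.5, n)
        b = 0.6
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(0.3 + b * lp)))).astype(float)
        cal = citl_and_slope(1 / (1 + np.exp(-lp)), y)
        assert cal.slope == pytest.approx(b, abs=3 * 0.02)


class TestHosmerLemeshow:
    def test_matches_hand_summation_on_three_bin_toy(self):
        pred = np.array([0.1] * 4 + [0.5] * 4 + [0.8] * 4)
        y = np.array([0, 0, 0, 1, 0, 0, 1, 1, 1, 1, 1, 0])
        chi2, df, p, used = hosmer_lemeshow(pred, y, groups=3, df_policy="fitted")
        expected = 0.0
        for lo, hi in ((0, 4), (4, 8), (8, 12)):
            e1 = pred[lo:hi].sum()
            e0 = (1 - pred[lo:hi]).sum()
            o1 = y[lo:hi].sum()
            o0 = (1 - y[lo:hi]).sum()
            expected += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        assert used == 3
        assert df == 1
        assert chi2 == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(float(stats.chi2.sf(expected, 1)), abs=1e-12)

    def test_constant_predictions_degenerate(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.3] * 50, np.random.default_rng(0).integers(0, 2, 50))

    def test_gross_miscalibration_blows_up_chi2(self):
        rng = np.random.default_rng(31)
        n = 2000
        p_true = 1 / (1 + np.exp(-rng.normal(-0.8, 1.0, n)))
        y = (rng.uniform(size=n) < p_true).astype(float)
        # systematic underestimation: report a tenth of the true risk
        chi2, df, _, _ = hosmer_lemeshow(p_true / 10, y, groups=10)
        assert chi2 > 100 * df

    def test_p_values_uniform_under_correct_calibration(self):
        rng = np.random.default_rng(32)
        pvals = []
        for _ in range(300):
            p = rng.uniform(0.05, 0.6, 800)
            y = (rng.uniform(size=800) < p).astype(float)
            # true probabilities, nothing estimated: df = groups
            pvals.append(hosmer_lemeshow(p, y, groups=10, df_policy="external")[2])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_duplicate_cutpoints_merge_groups(self):
        pred = np.array([0.1] * 30 + [0.5] * 5 + [0.8] * 5)
        y = (np.arange(40) % 3 == 0).astype(float)
        _, _, _, used = hosmer_lemeshow(pred, y, groups=10)
        assert used < 10
        # two distinct values collapse onto a single quantile bin -> error
        with pytest.raises(ValueError):
            hosmer_lemeshow(np.array([0.1] * 30 + [0.8] * 10), y, groups=10)


class TestCalibrationCurve:
    def test_all_event_bin_has_observed_rate_one(self):
        pred = np.array([0.1] * 5 + [0.9] * 5)
        y = np.array([0] * 5 + [1] * 5)
        curve = calibration_curve(pred, y, groups=2)
        assert curve.iloc[-1]["observed_rate"] == 1.0

    def test_one_bin_per_distinct_prediction(self):
        pred = np.linspace(0.1, 0.9, 8)
        y = np.array([0, 1] * 4)
        curve = calibration_curve(pred, y, groups=8)
        assert (curve["n"] == 1).all()

    def test_near_diagonal_when_calibrated(self):
        rng = np.random.default_rng(41)
        p = rng.uniform(0.05, 0.6, 20000)
        y = (rng.uniform(size=20000) < p).astype(float)
        curve = calibration_curve(p, y, groups=10)
        assert np.max(np.abs(curve["mean_pred"] - curve["observed_rate"])) < 0.03
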