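"""Wald-ratio, IVW, and Egger estimators against independent oracles."""

import numpy as np
import pytest

from twosmr import (
    InsufficientInstrumentsError,
    UndefinedRatioError,
    egger_multivariable,
    ivw_multivariable,
    ivw_univariable,
    to_odds_ratio,
    wald_ratio,
)
from twosmr.simulate import SimConfig, simulate_panel
from conftest import random_panel


def normal_equations(B, by, se_y, intercept=False, se_scaling="multiplicative"):
    """Independent WLS oracle: explicit (X'WX)^-1 X'W y with SE scaling."""
    X = np.column_stack([np.ones(len(by)), B]) if intercept else B
    W = np.diag(1.0 / se_y**2)
    XtWX = X.T @ W @ X
    beta = np.linalg.solve(XtWX, X.T @ W @ by)
    resid = by - X @ beta
    rss = float(resid @ W @ resid)
    df = X.shape[0] - X.shape[1]
    scale = 1.0 if se_scaling == "fixed" else max(1.0, rss / df)
    se = np.sqrt(scale * np.diag(np.linalg.inv(XtWX)))
    return beta, se


class TestWaldRatio:
    def test_reproduces_printed_hdl_odds_ratio(self):
        """Per-allele CAD OR 0.90 with a 0.236-SD HDL-C effect gives OR 0.64 per SD."""
        by = np.log(0.90)
        bx = np.log(0.90) / np.log(0.64)
        se_y = (np.log(0.95) - np.log(0.86)) / (2 * 1.959963984540054)
        est = wald_ratio(by, se_y, bx, exposure="HDL-C")
        assert round(est.or_, 2) == 0.64

    def test_unit_exposure_reduces_to_outcome(self):
        est = wald_ratio(-0.1, 0.02, 1.0)
        assert est.or_ == pytest.approx(np.exp(-0.1))
        assert est.ci95[0] == pytest.approx(np.exp(-0.1 - 1.96 * 0.02), rel=1e-4)
        assert est.ci95[1] == pytest.approx(np.exp(-0.1 + 1.96 * 0.02), rel=1e-4)

    def test_null_outcome_gives_symmetric_ci_about_one(self):
        est = wald_ratio(0.0, 0.02, 0.5)
        assert est.or_ == pytest.approx(1.0)
        assert est.ci95[0] * est.ci95[1] == pytest.approx(1.0)

    def test_negative_exposure_effect_orders_ci(self):
        est = wald_ratio(0.1, 0.02, -0.5)
        assert est.ci95[0] < est.or_ < est.ci95[1]

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.1, 0.02, 0.0)


class TestOddsRatio:
    def test_null_effect(self):
        or_, ci = to_odds_ratio(0.0, 0.1)
        assert or_ == 1.0 and ci[0] < 1.0 < ci[1]

    def test_reproduces_printed_ldl_row(self):
        """theta = 0.4383, se = 0.0263 prints as OR 1.55 (1.47-1.63)."""
        or_, ci = to_odds_ratio(0.4383, 0.0263)
        assert round(or_, 2) == 1.55
        assert round(ci[0], 2) == 1.47
        assert round(ci[1], 2) == 1.63

    def test_sign_symmetry(self):
        or_pos, ci_pos = to_odds_ratio(0.3, 0.05)
        or_neg, ci_neg = to_odds_ratio(-0.3, 0.05)
        assert or_neg == pytest.approx(1 / or_pos)
        assert ci_neg[1] == pytest.approx(1 / ci_pos[0])


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        panel = random_panel(J=1, K=1, seed=1)
        est = ivw_univariable(panel)
        wald = wald_ratio(panel.by[0], panel.se_y[0], panel.B[0, 0])
        assert est.theta == pytest.approx(wald.theta)
        assert est.se_theta == pytest.approx(wald.se_theta)

    def test_equal_weights_closed_form(self):
        panel = random_panel(J=10, K=1, seed=2)
        panel.se_y[:] = 0.004
        est = ivw_univariable(panel, se_scaling="fixed")
        bx, by = panel.B[:, 0], panel.by
        assert est.theta == pytest.approx(np.sum(bx * by) / np.sum(bx**2))

    def test_duplicated_snp_same_theta_smaller_se(self):
        one = random_panel(J=1, K=1, seed=3)
        two = one.take([0, 0])
        two.rsids = np.array(["rs1", "rs1b"], dtype=object)
        e1 = ivw_univariable(one, se_scaling="fixed")
        e2 = ivw_univariable(two, se_scaling="fixed")
        assert e2.theta == pytest.approx(e1.theta)
        assert e2.se_theta < e1.se_theta

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("se_scaling", ["fixed", "multiplicative"])
    def test_matches_normal_equations_oracle(self, seed, se_scaling):
        panel = random_panel(J=50, K=3, seed=seed)
        ests = ivw_multivariable(panel, se_scaling=se_scaling)
        beta, se = normal_equations(panel.B, panel.by, panel.se_y, se_scaling=se_scaling)
        for k, est in enumerate(ests):
            assert est.theta == pytest.approx(beta[k], rel=1e-8)
            assert est.se_theta == pytest.approx(se[k], rel=1e-8)

    def test_matches_statsmodels_wls(self):
        """Independent library route (fixed-effect covariance)."""
        import statsmodels.api as sm

        panel = random_panel(J=40, K=2, seed=7)
        w = 1.0 / panel.se_y**2
        fit = sm.WLS(panel.by, panel.B, weights=w).fit()
        ests = ivw_multivariable(panel, se_scaling="fixed")
        for k, est in enumerate(ests):
            assert est.theta == pytest.approx(fit.params[k], rel=1e-10)
            model_se = fit.bse[k] / np.sqrt(fit.scale)  # statsmodels scales by RSS/df
            assert est.se_theta == pytest.approx(model_se, rel=1e-10)

    def test_nine_snp_locus_fixture_matches_oracle(self):
        panel = random_panel(J=9, K=1, seed=13)
        est = ivw_univariable(panel)
        beta, se = normal_equations(panel.B, panel.by, panel.se_y)
        assert est.theta == pytest.approx(beta[0], rel=1e-8)
        assert est.se_theta == pytest.approx(se[0], rel=1e-8)

    def test_insufficient_instruments(self):
        panel = random_panel(J=2, K=3, seed=1)
        with pytest.raises(InsufficientInstrumentsError):
            ivw_multivariable(panel)

    def test_se_rescaling_property(self):
        """Scaling all se_y by c leaves theta unchanged and scales fixed SEs by c."""
        panel = random_panel(J=30, K=2, seed=21)
        scaled = random_panel(J=30, K=2, seed=21)
        scaled.se_y = panel.se_y * 3.0
        a = ivw_multivariable(panel, se_scaling="fixed")
        b = ivw_multivariable(scaled, se_scaling="fixed")
        for ea, eb in zip(a, b):
            assert eb.theta == pytest.approx(ea.theta, rel=1e-10)
            assert eb.se_theta == pytest.approx(3.0 * ea.se_theta, rel=1e-10)


class TestEgger:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_normal_equations_oracle(self, seed):
        from twosmr.sumstats import orient_to_exposure

        panel = random_panel(J=50, K=3, seed=seed)
        est = egger_multivariable(panel, 0)
        oriented = orient_to_exposure(panel, 0)
        beta, se = normal_equations(oriented.B, oriented.by, oriented.se_y, intercept=True)
        assert est.intercept == pytest.approx(beta[0], rel=1e-8)
        assert est.theta == pytest.approx(beta[1], rel=1e-8)
        assert est.se_theta == pytest.approx(se[1], rel=1e-8)
        assert est.se_intercept == pytest.approx(se[0], rel=1e-8)

    def test_null_direct_effects_give_null_intercept(self):
        """Mean intercept over replicates sits within 2 MC SE of zero.

        Uses strong, consistently oriented instruments so the intercept
        estimand is exactly the (zero) mean direct effect.
        """
        from twosmr.simulate import STRONG_INSTRUMENTS

        n_rep = 100
        intercepts = np.empty(n_rep)
        for r in range(n_rep):
            panel, _ = simulate_panel(SimConfig(
                J=100, seed=1000 + r, direct_frac=0.0,
                gamma_density="dense", gamma_sign="positive", **STRONG_INSTRUMENTS,
            ))
            intercepts[r] = egger_multivariable(panel, 0).intercept
        mc_se = intercepts.std(ddof=1) / np.sqrt(n_rep)
        assert abs(intercepts.mean()) < 2 * mc_se

    def test_zero_residual_df_rejected(self):
        panel = random_panel(J=4, K=3, seed=5)
        with pytest.raises(InsufficientInstrumentsError):
            egger_multivariable(panel, 0)

    def test_slope_equals_ivw_when_intercept_vanishes(self):
        """Residuals W-orthogonal to both 1 and B force the same slope as IVW."""
        rng = np.random.default_rng(3)
        J = 30
        bx = np.abs(rng.normal(0.05, 0.02, size=J))  # already oriented
        se_y = rng.uniform(0.002, 0.005, size=J)
        w = 1.0 / se_y**2
        e = rng.standard_normal(J)
        X = np.column_stack([np.ones(J), bx])
        # project noise off the weighted column space of [1, bx]
        e = e - X @ np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * e))
        by = 0.4 * bx + e
        panel = random_panel(J=J, K=1, seed=0)
        panel.B = bx[:, None]
        panel.by = by
        panel.se_y = se_y
        ivw = ivw_univariable(panel, se_scaling="fixed")
        egger = egger_multivariable(panel, 0, se_scaling="fixed")
        assert egger.intercept == pytest.approx(0.0, abs=1e-12)
        assert egger.theta == pytest.approx(ivw.theta, rel=1e-10)
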