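"""R2* estimators: exact recoveries, closed-form OLS oracles, reductions."""

import numpy as np
import pytest

from r2hat.epgx import PoolSignal
from r2hat.fits import (
    AlphaLinearModel,
    EstaticsR2Star,
    LogLinearR2Star,
    MWFQuadratic,
    fit_alpha_linear_model,
    fit_estatics,
    fit_loglinear_r2star,
)
from r2hat.params import EchoTimes, two_pool_wm
from r2hat.signal_model import EchoTrain, synthesize_echo_train

TE = EchoTimes()
TE_S = TE.seconds


class TestLogLinear:
    def test_monoexponential_recovered_exactly(self):
        train = EchoTrain(np.exp(-TE.ms * 0.030), TE)
        fit = fit_loglinear_r2star(train)
        assert fit.r2star == pytest.approx(30.0, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_constant_train_gives_zero_rate(self):
        fit = fit_loglinear_r2star(EchoTrain(np.full(6, 0.7), TE))
        assert fit.r2star == pytest.approx(0.0, abs=1e-12)

    def test_biexponential_matches_normal_equations_oracle(self):
        """Slope equals the hand-assembled 2-parameter OLS solution of the
        logged samples (independent linear-algebra route)."""
        k = 0.8
        train = synthesize_echo_train(
            PoolSignal(0.16 * k, 0.84 * k), two_pool_wm(0.16), TE
        )
        y = np.log(train.values)
        design = np.stack([np.ones_like(TE_S), TE_S], axis=1)
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        fit = fit_loglinear_r2star(train)
        assert fit.r2star == pytest.approx(-beta[1], rel=1e-12)
        assert fit.ln_s0 == pytest.approx(beta[0], rel=1e-12)

    def test_nonpositive_samples_excluded_and_counted(self):
        values = np.exp(-TE.ms * 0.030)
        values[-1] = 0.0
        est = LogLinearR2Star().fit(TE, values)
        assert int(est.n_excluded_) == 1
        assert est.r2star_ == pytest.approx(30.0, abs=1e-9)

    def test_too_few_usable_echoes_fails(self):
        values = np.zeros(6)
        values[0] = 1.0
        with pytest.raises(ValueError, match="usable"):
            LogLinearR2Star().fit(TE, values)

    def test_vectorised_fit_matches_scalar(self):
        rng = np.random.default_rng(0)
        batch = np.exp(-TE.ms * rng.uniform(0.01, 0.06, size=(7, 1))) * rng.uniform(
            0.5, 2.0, size=(7, 1)
        )
        est = LogLinearR2Star().fit(TE, batch)
        for i in range(7):
            single = fit_loglinear_r2star(EchoTrain(batch[i], TE))
            assert est.r2star_[i] == pytest.approx(single.r2star, rel=1e-12)

    def test_predict_roundtrip(self):
        values = 0.9 * np.exp(-TE.ms * 0.025)
        est = LogLinearR2Star().fit(TE, values)
        assert np.allclose(est.predict(TE), values, rtol=1e-10)


class TestEstatics:
    def test_identical_decay_different_amplitudes(self):
        t1 = EchoTrain(1.0 * np.exp(-TE.ms * 0.030), TE)
        t2 = EchoTrain(0.4 * np.exp(-TE.ms * 0.030), TE)
        fit = fit_estatics([t1, t2])
        assert fit.r2star_common == pytest.approx(30.0, abs=1e-9)
        assert fit.intercepts[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.intercepts[1] == pytest.approx(np.log(0.4), abs=1e-12)

    def test_single_train_reduces_to_loglinear_bit_for_bit(self):
        k = 0.8
        train = synthesize_echo_train(
            PoolSignal(0.16 * k, 0.84 * k), two_pool_wm(0.16), TE
        )
        joint = EstaticsR2Star().fit([TE], [train.values])
        single = LogLinearR2Star().fit(TE, train.values)
        assert float(joint.r2star_) == float(single.r2star_)
        assert float(joint.ln_s0_[0]) == float(single.ln_s0_)

    def test_two_decays_match_block_normal_equations_oracle(self):
        """Shared slope with per-train intercepts, solved independently via
        an explicitly assembled block design matrix."""
        ya = np.log(0.9) - TE_S * 28.0
        yb = np.log(0.7) - TE_S * 34.0
        design = np.zeros((12, 3))
        design[:6, 0] = 1.0
        design[6:, 1] = 1.0
        design[:, 2] = -np.concatenate([TE_S, TE_S])
        beta, *_ = np.linalg.lstsq(design, np.concatenate([ya, yb]), rcond=None)
        fit = fit_estatics(
            [EchoTrain(np.exp(ya), TE), EchoTrain(np.exp(yb), TE)]
        )
        assert fit.r2star_common == pytest.approx(beta[2], rel=1e-10)
        assert fit.intercepts == pytest.approx(tuple(beta[:2]), rel=1e-10)

    def test_joint_slope_lies_between_individual_slopes(self):
        ta = EchoTrain(np.exp(-TE.ms * 0.028), TE)
        tb = EchoTrain(np.exp(-TE.ms * 0.034), TE)
        joint = fit_estatics([ta, tb]).r2star_common
        assert 28.0 < joint < 34.0


class TestAlphaLinearModel:
    ALPHAS = np.array([6.0, 9.0, 12.0, 15.0, 19.0, 26.0, 31.0, 36.0, 42.0])

    def test_exact_line_recovered(self):
        r2 = 30.0 + 0.2 * self.ALPHAS
        fit = fit_alpha_linear_model(r2, self.ALPHAS)
        assert fit.r2star_hat == pytest.approx(30.0, abs=1e-10)
        assert fit.dr2star_dalpha == pytest.approx(0.2, abs=1e-12)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)

    def test_constant_values_give_zero_slope(self):
        fit = fit_alpha_linear_model(np.full(9, 31.0), self.ALPHAS)
        assert fit.dr2star_dalpha == pytest.approx(0.0, abs=1e-12)
        assert fit.r2star_hat == pytest.approx(31.0)

    def test_b1_scales_the_effective_angle(self):
        r2 = 30.0 + 0.2 * (self.ALPHAS * 0.8)
        fit = fit_alpha_linear_model(r2, self.ALPHAS, b1=0.8)
        assert fit.r2star_hat == pytest.approx(30.0, abs=1e-10)
        assert fit.dr2star_dalpha == pytest.approx(0.2, abs=1e-12)

    def test_degenerate_angles_rejected(self):
        with pytest.raises(ValueError):
            AlphaLinearModel().fit([26.0], [30.0])
        with pytest.raises(ValueError, match="distinct"):
            AlphaLinearModel().fit([26.0, 26.0], [30.0, 31.0])

    def test_invalid_b1_rejected(self):
        with pytest.raises(ValueError, match="B1"):
            AlphaLinearModel().fit([6.0, 26.0], [30.0, 34.0], b1=-1.0)

    def test_voxelwise_b1_broadcast(self):
        b1 = np.array([0.8, 1.0, 1.2])
        r2 = 30.0 + 0.2 * (b1[:, None] * self.ALPHAS)
        est = AlphaLinearModel().fit(self.ALPHAS, r2, b1)
        assert np.allclose(est.r2star_hat_, 30.0, atol=1e-9)
        assert np.allclose(est.dr2star_dalpha_, 0.2, atol=1e-11)


class TestMWFQuadratic:
    MWF = np.arange(0.02, 0.2001, 0.02)

    def test_exact_quadratic_recovered_and_inverts(self):
        slopes = 2.0 * self.MWF + 5.0 * self.MWF**2
        model = MWFQuadratic().fit(self.MWF, slopes)
        assert model.beta1_ == pytest.approx(2.0, rel=1e-9)
        assert model.beta2_ == pytest.approx(5.0, rel=1e-9)
        for m, s in zip(self.MWF, slopes):
            assert model.invert(s) == pytest.approx(m, rel=1e-9)

    def test_zero_slopes_give_zero_coefficients(self):
        model = MWFQuadratic().fit(self.MWF, np.zeros_like(self.MWF))
        assert model.beta1_ == pytest.approx(0.0, abs=1e-12)
        assert model.beta2_ == pytest.approx(0.0, abs=1e-12)

    def test_grid_slopes_match_independent_polyfit_oracle(self, grid_r2, grid):
        """Fitted curve agrees with an origin-constrained fit assembled via
        numpy lstsq on the simulated slope-vs-MWF data (residency 300 ms)."""
        from r2hat.grid import linear_model_components

        _, slope, _ = linear_model_components(grid_r2, grid.alphas_deg)
        s300 = slope[:, 2]
        model = MWFQuadratic().fit(self.MWF, s300)
        design = np.stack([self.MWF, self.MWF**2], axis=1)
        beta, *_ = np.linalg.lstsq(design, s300, rcond=None)
        assert model.beta1_ == pytest.approx(beta[0], rel=1e-9)
        assert model.beta2_ == pytest.approx(beta[1], rel=1e-9)
        rms_rel = np.sqrt(np.mean((model.predict(self.MWF) / s300 - 1.0) ** 2))
        assert rms_rel < 0.25  # near-quadratic dependence on MWF

    def test_inversion_failure_is_diagnosed(self):
        model = MWFQuadratic().fit(self.MWF, 2.0 * self.MWF + 5.0 * self.MWF**2)
        with pytest.raises(ValueError, match="root"):
            model.invert(-3.0)

    def test_get_params_roundtrip(self):
        # scikit-learn estimator contract
        est = LogLinearR2Star(positivity_floor=1e-10)
        assert LogLinearR2Star(**est.get_params()).positivity_floor == 1e-10
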