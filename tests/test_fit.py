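"""The robust loss, its normal expectation, the profile residual, and the
joint (β, τ²) estimation."""

import numpy as np
import pytest
from scipy import stats

from mrprofile import (
    RobustLoss,
    SharedCorrelation,
    SNPRecord,
    compute_eta,
    fit_effects,
    profile_t,
    tukey_rho,
)
from mrprofile.fit import profile_t_vec, tukey_psi

from .conftest import study_from_arrays


class TestTukeyRho:
    def test_zero_residual(self):
        assert tukey_rho(0.0, 4.6851) == 0.0

    def test_saturation_beyond_c(self):
        c = 4.6851
        # c²/6 = 3.6583603…: every residual beyond c contributes the same
        assert tukey_rho(c, c) == pytest.approx(c * c / 6)
        assert tukey_rho(100.0, c) == pytest.approx(3.6583603, abs=1e-6)
        assert tukey_rho(-100.0, c) == tukey_rho(100.0, c)

    def test_quadratic_near_zero(self):
        # ρ(r)/(r²/2) = 1 − (r/c)² + O(r⁴); at r = 1e-3 the deviation is ~5e-8
        r = 1e-3
        assert tukey_rho(r, 4.6851) / (r * r / 2) == pytest.approx(1.0, abs=1e-6)

    def test_nondecreasing_in_abs_r(self):
        r = np.linspace(0, 10, 500)
        vals = tukey_rho(r, 2.5)
        assert np.all(np.diff(vals) >= -1e-15)

    def test_psi_is_derivative(self):
        r = np.linspace(-6, 6, 41)
        h = 1e-7
        numeric = (tukey_rho(r + h, 3.0) - tukey_rho(r - h, 3.0)) / (2 * h)
        np.testing.assert_allclose(tukey_psi(r, 3.0), numeric, atol=1e-6)


class TestEta:
    def test_large_c_limit_is_half(self):
        # η → 1/2 like 1.5/c² (quadratic-loss limit, E[Z²]/2)
        assert compute_eta(30.0) == pytest.approx(0.5, abs=2e-3)
        assert compute_eta(300.0) == pytest.approx(0.5, abs=2e-5)

    def test_small_c_limit_is_zero(self):
        assert compute_eta(1e-3) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("c", [0.5, 1.0, 3.0, 4.6851])
    def test_matches_closed_form_truncated_moment_oracle(self, c):
        # independent oracle: eta = c²/6·P(|Z|>c) + Σ moments of Z·1{|Z|≤c}
        # with I_k = ∫_{-c}^c z^{2k} φ(z) dz by the recurrence
        # I_k = (2k−1)·I_{k−1} − 2·c^{2k−1}·φ(c)
        phi_c = stats.norm.pdf(c)
        I0 = 1 - 2 * stats.norm.sf(c)
        I1 = I0 - 2 * c * phi_c
        I2 = 3 * I1 - 2 * c ** 3 * phi_c
        I3 = 5 * I2 - 2 * c ** 5 * phi_c
        oracle = c * c / 6 * (1 - I0) + (3 * I1 - 3 * I2 / c ** 2 + I3 / c ** 4) / 6
        assert compute_eta(c) == pytest.approx(oracle, abs=1e-8)

    def test_eta_in_open_interval(self):
        loss = RobustLoss(c=4.6851)
        assert 0 < loss.eta < 0.5


class TestProfileT:
    def _record(self, Gamma=0.12, gamma=0.2, se_G=0.05, se_g=0.02):
        return SNPRecord(snp_id="rs1", effect_allele="A", other_allele="G",
                         gamma_hat=np.array([gamma]), se_gamma=np.array([se_g]),
                         Gamma_hat=Gamma, se_Gamma=se_G,
                         sel_pvalues=np.array([0.5]))

    def test_beta_zero_reduces_to_outcome_z(self):
        rec = self._record()
        sigma = SharedCorrelation.identity(1)
        assert profile_t(rec, np.array([0.0]), 0.0, sigma) == \
            pytest.approx(0.12 / 0.05)

    def test_hand_arithmetic_k1_no_correlation(self):
        # t = (0.12 − 0.5·0.2)/√(0.05² + 0.25·0.02²) = 0.02/√0.0026
        rec = self._record()
        sigma = SharedCorrelation.identity(1)
        t = profile_t(rec, np.array([0.5]), 0.0, sigma)
        assert t == pytest.approx(0.02 / np.sqrt(0.0026), abs=1e-10)
        assert t == pytest.approx(0.392232, abs=1e-6)

    @pytest.mark.parametrize("theta,b", [(0.0, 0.5), (0.4, 0.8), (-0.6, 1.5)])
    def test_denominator_matches_monte_carlo_variance(self, theta, b, rng):
        # Var(Γ̂ − bγ̂) under the correlated sampling law, by simulation
        se_G, se_g = 0.07, 0.03
        cov = np.array([[se_G ** 2, theta * se_G * se_g],
                        [theta * se_G * se_g, se_g ** 2]])
        draws = rng.multivariate_normal([0.0, 0.0], cov, size=400_000)
        mc_var = np.var(draws[:, 0] - b * draws[:, 1])
        analytic = se_G ** 2 + b ** 2 * se_g ** 2 - 2 * b * theta * se_G * se_g
        mc_se = mc_var * np.sqrt(2 / 400_000)
        assert analytic == pytest.approx(mc_var, abs=4 * mc_se)

    def test_nonpositive_variance_names_the_snp(self):
        # an entry > 1 cannot pass the SharedCorrelation constructor, so the
        # invalid Σ is forced directly onto the vectorized path
        with pytest.raises(ValueError, match="rs1"):
            profile_t_vec(np.array([0.12]), np.array([[0.2]]),
                          np.array([0.01]), np.array([[0.01]]),
                          np.array([1.0]), 0.0,
                          np.array([[1.0, 1.2], [1.2, 1.0]]),
                          snp_ids=["rs1"])


class TestFitEffects:
    def test_noiseless_consistency(self):
        rng = np.random.default_rng(3)
        gamma = rng.normal(0, 0.3, 50)
        beta0 = 0.7
        study = study_from_arrays(beta0 * gamma, 1e-4, gamma[:, None], 1e-4)
        fit = fit_effects(study=study)
        assert fit.beta_hat[0] == pytest.approx(beta0, abs=1e-6)
        assert fit.tau2_hat == pytest.approx(0.0, abs=1e-12)
        assert fit.converged

    def test_grid_search_oracle_k1(self, rng):
        gamma = rng.normal(0, 0.2, 120)
        Gamma = 0.5 * gamma + rng.normal(0, 0.02, 120)
        study = study_from_arrays(Gamma, 0.02, gamma[:, None], 0.015)
        fit = fit_effects(study=study)
        loss = RobustLoss()
        grid = np.linspace(fit.beta_hat[0] - 1, fit.beta_hat[0] + 1, 4001)
        obj = [np.sum(loss.rho(profile_t_vec(
            study.Gamma, study.gamma, study.se_Gamma, study.se_gamma,
            np.array([b]), fit.tau2_hat, np.eye(2)))) for b in grid]
        b_star = grid[int(np.argmin(obj))]
        step = grid[1] - grid[0]
        assert abs(fit.beta_hat[0] - b_star) <= step

    def test_scale_equivariance(self, rng):
        gamma = rng.normal(0, 0.2, 80)
        Gamma = 0.4 * gamma + rng.normal(0, 0.02, 80)
        base = study_from_arrays(Gamma, 0.02, gamma[:, None], 0.015)
        a = 2.5
        scaled = study_from_arrays(Gamma, 0.02, (a * gamma)[:, None], a * 0.015)
        f_base = fit_effects(study=base)
        f_scaled = fit_effects(study=scaled)
        assert f_scaled.beta_hat[0] == pytest.approx(f_base.beta_hat[0] / a,
                                                     rel=1e-6)

    def test_bounded_influence_of_single_outlier(self, rng):
        gamma = rng.normal(0, 0.2, 100)
        Gamma = 0.5 * gamma + rng.normal(0, 0.02, 100)
        study = study_from_arrays(Gamma, 0.02, gamma[:, None], 0.015)
        clean = fit_effects(study=study).beta_hat[0]
        shifts = []
        for bad in (1.0, 10.0, 1e3, 1e6):
            Gamma_c = Gamma.copy()
            Gamma_c[0] = bad
            corrupted = study_from_arrays(Gamma_c, 0.02, gamma[:, None], 0.015)
            shifts.append(abs(fit_effects(study=corrupted).beta_hat[0] - clean))
        # the induced shift stabilizes: an arbitrarily wild outlier cannot
        # move the estimate further than a moderately wild one
        assert shifts[-1] <= max(shifts[:2]) + 1e-3
        assert shifts[-1] < 0.05

    def test_multivariable_recovery(self):
        rng = np.random.default_rng(11)
        p, beta0 = 400, np.array([0.3, -0.2])
        gamma = rng.normal(0, 0.2, (p, 2))
        Gamma = gamma @ beta0 + rng.normal(0, 0.02, p)
        study = study_from_arrays(Gamma, 0.02, gamma, 0.01)
        fit = fit_effects(study=study)
        np.testing.assert_allclose(fit.beta_hat, beta0,
                                   atol=4 * fit.se.max() + 1e-3)
        assert np.all(fit.ci[:, 0] < fit.beta_hat)
        assert np.all(fit.beta_hat < fit.ci[:, 1])

    def test_too_few_instruments_is_hard_error(self):
        study = study_from_arrays([0.1], 0.01, [[0.2]], 0.01)
        with pytest.raises(ValueError, match="p > K"):
            fit_effects(study=study)

    def test_ci_contains_estimate_and_pvalues_valid(self, rng):
        gamma = rng.normal(0, 0.2, 60)
        Gamma = 0.2 * gamma + rng.normal(0, 0.03, 60)
        fit = fit_effects(study=study_from_arrays(Gamma, 0.03, gamma[:, None],
                                                  0.015))
        assert fit.ci[0, 0] < fit.beta_hat[0] < fit.ci[0, 1]
        assert 0 < fit.pvalues[0] <= 1
        assert fit.tau2_hat >= 0
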