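"""Post-estimation layer: technical efficiency, gamma, slack resources,
marginal effects and scenario arithmetic."""

import numpy as np
import pytest
from scipy import stats

from geosfa.effects import (
    build_effects_report,
    d_expected_te_dsigma,
    expected_slack_halfnormal,
    expected_te_halfnormal,
    marginal_effect_slack,
    marginal_effect_te,
    national_totals,
    scenario_savings,
    sigma_u_at_means,
    slack_from_u,
    slack_resources,
    technical_efficiency,
    variance_ratio_gamma,
)
from geosfa.panel import BINARY_COVARIATES


class TestTechnicalEfficiency:
    def test_zero_inefficiency_gives_unit_te(self, fitted):
        draws, design, _ = fitted
        import copy
        d0 = copy.copy(draws)
        d0.u_star = np.zeros_like(draws.u_star)
        te, overall = technical_efficiency(d0, design)
        assert np.allclose(te, 1.0)
        assert overall == pytest.approx(1.0)

    def test_closed_form_against_monte_carlo(self, rng):
        # E[exp(-u)] for half-normal scale 1: 2 e^{1/2} Phi(-1) = 0.5232
        closed = expected_te_halfnormal(1.0)
        assert closed == pytest.approx(2 * np.e ** 0.5 * stats.norm.cdf(-1),
                                       abs=1e-12)
        assert closed == pytest.approx(0.5232, abs=5e-4)
        u = np.abs(rng.standard_normal(100000))
        mc = np.exp(-u).mean()
        se = np.exp(-u).std() / np.sqrt(1e5)
        assert closed == pytest.approx(mc, abs=3 * se)

    def test_te_strictly_decreasing_in_sigma(self):
        grid = np.linspace(0.05, 4.0, 60)
        vals = expected_te_halfnormal(grid)
        assert np.all(np.diff(vals) < 0)
        assert np.all((vals > 0) & (vals <= 1))

    def test_fitted_te_in_unit_interval(self, fitted):
        draws, design, _ = fitted
        te, overall = technical_efficiency(draws, design)
        assert np.all(te > 0) and np.all(te <= 1)
        assert 0 < overall < 1

    def test_te_tracks_simulated_truth(self, fitted):
        from scipy.stats import spearmanr
        draws, design, truth = fitted
        te, _ = technical_efficiency(draws, design)
        rho = spearmanr(te, truth.te).statistic
        assert rho > 0.5  # short reference chain, small panel


class TestGamma:
    def test_published_variance_components(self):
        # in-table arithmetic of the variance ratio
        assert variance_ratio_gamma(2.301, 0.142) == pytest.approx(0.9419,
                                                                   abs=5e-5)
        assert variance_ratio_gamma(0.439, 0.141) == pytest.approx(0.7569,
                                                                   abs=5e-5)

    def test_symmetry_point(self):
        assert variance_ratio_gamma(0.7, 0.7) == pytest.approx(0.5)

    def test_positivity_guard(self):
        with pytest.raises(ValueError):
            variance_ratio_gamma(-1.0, 0.5)


class TestSlack:
    def test_zero_inefficiency_zero_slack(self):
        assert slack_from_u(0.0, 0.4, 10.0) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # u = 0.3, elasticity 0.397, input level 10
        val = slack_from_u(0.3, 0.397, 10.0)
        assert val == pytest.approx(10 * (1 - np.exp(-0.3 / 0.397)), abs=1e-9)
        assert val == pytest.approx(5.30, abs=0.01)

    def test_monotonicity_grid(self):
        u_grid = np.linspace(0, 2, 30)
        s = slack_from_u(u_grid, 0.4, 1.0)
        assert np.all(np.diff(s) > 0)
        betas = np.linspace(0.1, 2.0, 20)
        vals = [slack_from_u(0.5, b, 1.0) for b in betas]
        assert np.all(np.diff(vals) < 0)

    def test_never_exceeds_input_level(self):
        assert slack_from_u(1e6, 0.01, 7.0) <= 7.0

    def test_nonpositive_elasticity_refused(self):
        with pytest.raises(ValueError, match="elasticity"):
            slack_from_u(0.5, -0.1, 1.0)

    def test_average_hospital_distribution(self, fitted):
        draws, design, _ = fitted
        s = slack_resources(draws, design, "log_mor_star", 8.0,
                            at="average_hospital")
        assert s.shape == (draws.n_draws,)
        assert np.all((s >= 0) & (s <= 8.0))

    def test_per_observation_national_totals(self, fitted):
        draws, design, _ = fitted
        x = np.full(design.n_obs, 5.0)
        s = slack_resources(draws, design, "log_mor_star", x,
                            at="per_observation")
        assert np.all((s >= 0) & (s <= 5.0))
        tot = national_totals(s, design)
        assert sum(tot.values()) == pytest.approx(float(s.sum()), abs=1e-9)


class TestMarginalEffects:
    def test_zero_delta_zero_effect(self, fitted):
        draws, design, _ = fitted
        import copy
        d0 = copy.copy(draws)
        d0.delta = draws.delta.copy()
        j = design.z_names.index("Teach")
        d0.delta[:, j] = 0.0
        assert marginal_effect_te(d0, design, "Teach") == pytest.approx(0.0)

    def test_sign_opposite_to_delta(self, fitted):
        # inefficiency-reducing covariates raise expected efficiency
        draws, design, _ = fitted
        for cov in design.z_names:
            dbar = draws.delta[:, design.z_names.index(cov)].mean()
            eff = marginal_effect_te(draws, design, cov, mode="derivative")
            if abs(dbar) > 1e-8:
                assert np.sign(eff) == -np.sign(dbar)

    def test_derivative_matches_finite_difference(self, fitted):
        draws, design, _ = fitted
        j = design.z_names.index("SUCert")
        dj = draws.delta[:, j]
        sig = sigma_u_at_means(draws, design)
        eff = marginal_effect_te(draws, design, "SUCert", mode="derivative",
                                 times100=False)
        h = 1e-6
        fd = np.mean((expected_te_halfnormal(sig * np.exp(dj * h))
                      - expected_te_halfnormal(sig * np.exp(-dj * h)))
                     / (2 * h))
        assert eff == pytest.approx(fd, abs=1e-6)

    def test_slack_effect_sign_and_fd(self, fitted):
        draws, design, _ = fitted
        te_eff = marginal_effect_te(draws, design, "SUCert")
        sl_eff = marginal_effect_slack(draws, design, "SUCert",
                                       "log_mor_star", 8.0)
        assert np.sign(sl_eff) == -np.sign(te_eff)
        # finite difference on the closed-form expected slack
        j = design.z_names.index("SUCert")
        dj = draws.delta[:, j]
        sig = sigma_u_at_means(draws, design)
        k = design.x_names.index("log_mor_star")
        bk = float(draws.beta[:, k].mean())
        h = 1e-6
        fd = np.mean((expected_slack_halfnormal(sig * np.exp(dj * h), bk, 8.0)
                      - expected_slack_halfnormal(sig * np.exp(-dj * h), bk,
                                                  8.0)) / (2 * h))
        assert sl_eff == pytest.approx(fd, abs=1e-5)

    def test_discrete_mode_for_binary(self, fitted):
        draws, design, _ = fitted
        eff = marginal_effect_te(draws, design, "SUCert", mode="discrete")
        assert np.isfinite(eff)

    def test_derivative_of_closed_form(self):
        grid = np.linspace(0.1, 3.0, 25)
        h = 1e-6
        fd = (expected_te_halfnormal(grid + h)
              - expected_te_halfnormal(grid - h)) / (2 * h)
        assert np.allclose(d_expected_te_dsigma(grid), fd, atol=1e-6)
        assert np.all(d_expected_te_dsigma(grid) < 0)


class TestScenario:
    def test_noncert_stroke_unit_shift(self):
        raw, rounded = scenario_savings(0.401, 937)
        assert raw == pytest.approx(375.737)
        assert rounded == 376

    def test_cert_stroke_unit_shift(self):
        raw, rounded = scenario_savings(0.927, 937)
        assert raw == pytest.approx(868.599)
        assert int(raw) == 868  # integer part, as printed

    def test_zero_effect(self):
        assert scenario_savings(0.0, 937) == (0.0, 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            scenario_savings(-0.1, 10)


def test_effects_report_bundle(fitted):
    draws, design, _ = fitted
    rep = build_effects_report(
        draws, design,
        input_levels={"log_mor_star": 8.0, "log_phys": 30.0},
        binary_covariates=set(BINARY_COVARIATES))
    rep.validate()
    assert 0 < rep.te_overall <= 1
    assert 0 < rep.gamma < 1
    assert set(rep.slack_average) == {"log_mor_star", "log_phys"}
    assert rep.marginal_slack.shape[0] == len(design.z_names)
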