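"""Model specification, predictors and composed-error likelihoods."""

import numpy as np
import pytest
from scipy import integrate, stats

from geosfa.model import (
    EQ7_COVARIATES,
    MCMCSettings,
    ModelDesign,
    ModelSpec,
    ParameterState,
    build_design,
    eta_u,
    eta_y,
    alpha_of,
    loglik_conditional,
    loglik_marginal,
    skewnormal_loglik,
)
from geosfa.presets import get_preset, preset_names


class TestModelSpec:
    def test_json_round_trip(self):
        spec = get_preset("model8")
        again = ModelSpec.from_json(spec.to_json())
        assert again == spec

    def test_invalid_forms_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(functional_form="quadratic")
        with pytest.raises(ValueError):
            ModelSpec(struct_level="country")
        with pytest.raises(ValueError):
            ModelSpec(functional_form="translog", frontier_inputs=[])

    def test_mcmc_bookkeeping_validation(self):
        with pytest.raises(ValueError):
            MCMCSettings(iterations=1000, burn_in=2000)
        with pytest.raises(ValueError):
            MCMCSettings(iterations=1001, burn_in=0, thinning=100)

    def test_preset_nesting(self):
        # the input-notion variants are configuration of one machinery
        m2, m8, m9 = (get_preset(n) for n in ("model2", "model8", "model9"))
        assert set(m8.frontier_columns()) < set(m2.frontier_columns())
        assert set(m9.frontier_columns()) < set(m2.frontier_columns())
        assert {"log_phys", "log_nurse"} <= set(m8.ineff_covariates)
        assert {"D_mor", "log_mor_star"} <= set(m9.ineff_covariates)
        assert len(preset_names()) == 17

    def test_coarse_requires_coarse_map(self, prepared):
        panel, graph, _ = prepared
        import dataclasses
        bare = dataclasses.replace(graph, coarse_map=None)
        with pytest.raises(ValueError, match="coarse"):
            build_design(panel, bare, get_preset("model5"))


def _state_for(design, beta=None, delta=None, **kw):
    p, q = design.X.shape[1], design.Z.shape[1]
    return ParameterState(
        beta=np.zeros(p) if beta is None else beta,
        delta=np.zeros(q) if delta is None else delta,
        f_struct=np.zeros(design.struct_graph.n_regions)
        if design.struct_graph else None,
        f_unstruct=np.zeros(design.unstruct_graph.n_regions)
        if design.unstruct_graph else None,
        u_star=np.zeros(design.n_obs), **kw)


class TestPredictors:
    def test_eta_y_at_sample_means(self, prepared):
        # centered design: a record at sample means in the reference
        # wave reduces to the intercept, a zero-mortality record adds
        # the dummy coefficient (0.470 - 0.329 = 0.141)
        panel, graph, _ = prepared
        design = build_design(panel, graph, get_preset("model2"))
        beta = np.zeros(design.X.shape[1])
        beta[design.x_names.index("const")] = 0.470
        beta[design.x_names.index("D_mor")] = -0.329
        x_mean = np.zeros(design.X.shape[1])
        x_mean[design.x_names.index("const")] = 1.0
        assert float(x_mean @ beta) == pytest.approx(0.470)
        x_mean[design.x_names.index("D_mor")] = 1.0
        assert float(x_mean @ beta) == pytest.approx(0.141, abs=1e-12)

    def test_translog_nests_cobb_douglas(self, prepared):
        panel, graph, _ = prepared
        d_cd = build_design(panel, graph, get_preset("model2"))
        d_tl = build_design(panel, graph, get_preset("model10"))
        p_cd = d_cd.X.shape[1]
        assert d_tl.x_names[:p_cd - 4] == d_cd.x_names[:p_cd - 4]
        beta_tl = np.zeros(d_tl.X.shape[1])
        beta_cd = np.zeros(p_cd)
        rng = np.random.default_rng(1)
        vals = rng.standard_normal(p_cd)
        for i, nm in enumerate(d_cd.x_names):
            beta_cd[i] = vals[i]
            beta_tl[d_tl.x_names.index(nm)] = vals[i]
        s_cd = _state_for(d_cd, beta=beta_cd)
        s_tl = _state_for(d_tl, beta=beta_tl)
        assert np.allclose(eta_y(s_cd, d_cd), eta_y(s_tl, d_tl))

    def test_eta_u_neutral_gives_alpha_one(self, prepared):
        panel, graph, _ = prepared
        design = build_design(panel, graph, get_preset("model2"))
        st_ = _state_for(design)
        assert np.allclose(alpha_of(st_, design), 1.0)

    def test_certification_multiplies_alpha(self, prepared):
        panel, graph, _ = prepared
        design = build_design(panel, graph, get_preset("model2"))
        j = design.z_names.index("SUCert")
        delta = np.zeros(design.Z.shape[1])
        delta[j] = -1.167
        st_ = _state_for(design, delta=delta)
        a = alpha_of(st_, design)
        flipped = design.Z[:, j] + 1.0  # one more unit of certification
        ratio = np.exp(delta[j] * 1.0)
        design2_alpha = np.exp(design.Z @ delta + delta[j])
        assert np.allclose(design2_alpha / a, ratio)
        assert ratio == pytest.approx(np.exp(-1.167), abs=1e-12)
        assert np.exp(-1.167) == pytest.approx(0.311, abs=5e-4)

    def test_eta_u_additivity(self, prepared):
        panel, graph, _ = prepared
        design = build_design(panel, graph, get_preset("model2"))
        rng = np.random.default_rng(3)
        d1, d2 = np.zeros(design.Z.shape[1]), np.zeros(design.Z.shape[1])
        d1[0], d2[1] = rng.normal(), rng.normal()
        e1 = eta_u(_state_for(design, delta=d1), design)
        e2 = eta_u(_state_for(design, delta=d2), design)
        e12 = eta_u(_state_for(design, delta=d1 + d2), design)
        assert np.allclose(e12, e1 + e2, atol=1e-12)


class TestConditionalLikelihood:
    def _tiny_design(self, y):
        spec = ModelSpec(name="t", frontier_inputs=[], ineff_covariates=[],
                         struct_level=None, unstruct_level=None)
        n = len(y)
        return ModelDesign(
            y=np.asarray(y, float), X=np.ones((n, 1)), x_names=["const"],
            Z=np.zeros((n, 0)), z_names=[], z_means=np.zeros(0),
            struct_graph=None, struct_idx=None, unstruct_graph=None,
            unstruct_idx=None, unstruct_observed=None,
            hospital_ids=list(range(n)), hospital_idx=np.arange(n),
            wave_of_obs=np.full(n, 2006), spec=spec)

    def test_exact_fit_gives_constant_terms(self):
        d = self._tiny_design([1.0, 1.0])
        st_ = ParameterState(beta=np.array([2.0]), delta=np.zeros(0),
                             u_star=np.array([1.0, 1.0]), sigma_v2=0.25)
        # y - eta_y + alpha u* = 1 - 2 + 1 = 0 for each observation
        expect = 2 * (-0.5 * np.log(2 * np.pi * 0.25))
        assert loglik_conditional(st_, d) == pytest.approx(expect, abs=1e-12)

    def test_hand_value_single_observation(self):
        d = self._tiny_design([0.5])
        st_ = ParameterState(beta=np.array([0.0]), delta=np.zeros(0),
                             u_star=np.array([0.0]), sigma_v2=0.25)
        expect = -0.5 * np.log(2 * np.pi * 0.25) - 0.5
        assert loglik_conditional(st_, d) == pytest.approx(expect, abs=1e-12)

    def test_order_invariance(self, rng):
        y = rng.standard_normal(6)
        d1 = self._tiny_design(y)
        d2 = self._tiny_design(y[::-1].copy())
        st1 = ParameterState(beta=np.array([0.3]), delta=np.zeros(0),
                             u_star=np.abs(rng.standard_normal(6)))
        st2 = ParameterState(beta=st1.beta, delta=np.zeros(0),
                             u_star=st1.u_star[::-1].copy())
        assert loglik_conditional(st1, d1) == pytest.approx(
            loglik_conditional(st2, d2), abs=1e-12)

    def test_nonpositive_variance_rejected(self):
        d = self._tiny_design([0.0])
        st_ = ParameterState(beta=np.array([0.0]), delta=np.zeros(0),
                             u_star=np.array([0.0]), sigma_v2=1.0)
        st_.sigma_v2 = -1.0
        with pytest.raises(ValueError):
            loglik_conditional(st_, d)


class TestMarginalLikelihood:
    def test_gaussian_limit(self):
        eps = np.array([-0.7, 0.2, 1.1])
        ll = skewnormal_loglik(eps, 0.5, np.full(3, 1e-10))
        assert np.allclose(ll, stats.norm.logpdf(eps, 0, np.sqrt(0.5)),
                           atol=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sv = rng.uniform(0.2, 1.5)
        su = rng.uniform(0.1, 2.0)
        eps = rng.uniform(-2.5, 2.5)

        def integrand(u):
            return (stats.norm.pdf(eps + u, 0, sv)
                    * 2 * stats.norm.pdf(u, 0, su))
        val, _ = integrate.quad(integrand, 0, np.inf)
        closed = float(np.exp(skewnormal_loglik(np.array([eps]), sv ** 2,
                                                np.array([su]))[0]))
        assert closed == pytest.approx(val, abs=1e-8)

    @pytest.mark.parametrize("sv,su", [(0.5, 0.3), (1.0, 2.0), (0.3, 1.2)])
    def test_density_integrates_to_one(self, sv, su):
        tot, _ = integrate.quad(
            lambda e: float(np.exp(skewnormal_loglik(np.array([e]), sv ** 2,
                                                     np.array([su]))[0])),
            -20, 20)
        assert tot == pytest.approx(1.0, abs=1e-7)

    def test_extreme_residual_no_underflow(self):
        ll = skewnormal_loglik(np.array([40.0, -40.0]), 1.0,
                               np.array([1.0, 1.0]))
        assert np.all(np.isfinite(ll))

    def test_monte_carlo_consistency_with_conditional(self, rng):
        # averaging the conditional likelihood over u* prior draws
        # converges to the marginal
        sv2, su = 0.3, 0.8
        alpha = 1.3
        eps = 0.4
        u = np.abs(rng.standard_normal(400000)) * su
        cond = stats.norm.pdf(eps + alpha * u, 0, np.sqrt(sv2))
        mc = np.log(cond.mean())
        closed = float(skewnormal_loglik(np.array([eps]), sv2,
                                         np.array([su * alpha]))[0])
        assert mc == pytest.approx(closed, abs=0.01)

    def test_marginal_requires_halfnormal(self, prepared):
        panel, graph, _ = prepared
        spec = get_preset("model2", mu_star=0.5)
        design = build_design(panel, graph, spec)
        st_ = _state_for(design)
        with pytest.raises(ValueError, match="mu_star"):
            loglik_marginal(st_, design)

    def test_alpha_exp_sum_identity(self, prepared):
        panel, graph, _ = prepared
        design = build_design(panel, graph, get_preset("model2"))
        rng = np.random.default_rng(5)
        delta = rng.normal(0, 0.2, design.Z.shape[1])
        st_ = _state_for(design, delta=delta)
        a = alpha_of(st_, design)
        prod = np.ones(design.n_obs)
        for j in range(design.Z.shape[1]):
            prod *= np.exp(design.Z[:, j] * delta[j])
        assert np.allclose(a, prod, rtol=1e-12)
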