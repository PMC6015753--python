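import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isomix.io import Factor, MixtureData
from isomix.model import (
    EffectDesign,
    ErrorSpec,
    ModelSpec,
    ParameterState,
    TracerDataset,
    ilr_basis,
    ilr_dirichlet_logpdf,
    ilr_transform,
    individual_proportions,
    inverse_ilr,
    log_likelihood_pointwise,
    mixture_mean,
    mixture_scale,
)
from isomix.priors import DirichletPrior

from conftest import make_fixed_dataset, make_summary_sources


class TestIlr:
    def test_basis_orthonormal(self):
        for k in range(2, 9):
            v = ilr_basis(k)
            np.testing.assert_allclose(v.T @ v, np.eye(k - 1), atol=1e-12)
            np.testing.assert_allclose(v.sum(axis=0), 0.0, atol=1e-12)

    def test_k2_barycenter_maps_to_zero(self):
        assert ilr_transform(np.array([0.5, 0.5]))[0] == pytest.approx(0.0, abs=1e-14)

    def test_k3_barycenter(self):
        np.testing.assert_allclose(ilr_transform(np.full(3, 1 / 3)), 0.0, atol=1e-14)

    def test_norm_equals_aitchison_norm(self):
        # independent check: ||ilr(p)|| == ||clr(p)|| for an orthonormal basis
        p = np.array([0.6, 0.3, 0.1])
        clr = np.log(p) - np.log(p).mean()
        assert np.linalg.norm(ilr_transform(p)) == pytest.approx(np.linalg.norm(clr), abs=1e-12)

    def test_inverse_at_origin_is_uniform(self):
        np.testing.assert_allclose(inverse_ilr(np.zeros(3)), 0.25, atol=1e-14)

    def test_roundtrip(self):
        p = np.array([0.7, 0.2, 0.1])
        np.testing.assert_allclose(inverse_ilr(ilr_transform(p)), p, atol=1e-12)

    def test_large_coordinate_approaches_vertex(self):
        p = inverse_ilr(np.array([50.0, 0.0]))
        assert p.sum() == pytest.approx(1.0)
        assert p[0] > 1 - 1e-12 and np.all(p > 0)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            ilr_transform(np.array([1.0, 0.0]))

    def test_not_simplex_rejected(self):
        with pytest.raises(ValueError):
            ilr_transform(np.array([0.5, 0.4]))

    def test_nonfinite_z_rejected(self):
        with pytest.raises(ValueError):
            inverse_ilr(np.array([np.inf, 0.0]))

    @given(
        k=st.integers(2, 8),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=80, deadline=None)
    def test_roundtrip_property(self, k, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(k) * 2) + 1e-9
        p /= p.sum()
        z = ilr_transform(p)
        back = inverse_ilr(z)
        np.testing.assert_allclose(back, p, atol=1e-12)
        assert back.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dirichlet_pushforward_integrates_to_one(self):
        # validates the sqrt(K) * prod(p) Jacobian for K=2 numerically
        alpha = np.array([2.0, 3.0])
        z = np.linspace(-12, 12, 20_001)[:, None]
        dens = np.exp([ilr_dirichlet_logpdf(zi, alpha) for zi in z])
        integral = np.trapezoid(dens, dx=z[1, 0] - z[0, 0])
        assert integral == pytest.approx(1.0, abs=1e-6)


class TestIndividualProportions:
    def _mixture(self):
        return MixtureData(
            values=np.zeros((6, 1)),
            tracer_names=["x"],
            fixed_factors=[Factor("Sex", np.array([0, 1, 0, 1, 0, 1]), ["F", "M"])],
            continuous_covariates=[("Length", np.array([10.0, 20, 30, 40, 50, 60]))],
        )

    def test_intercept_only_rows_equal(self):
        state = ParameterState(ilr_intercept=np.array([0.4, -0.2]))
        mix = MixtureData(values=np.zeros((5, 1)), tracer_names=["x"])
        p = individual_proportions(state, EffectDesign(), mix)
        expected = inverse_ilr(state.ilr_intercept)
        np.testing.assert_allclose(p, np.tile(expected, (5, 1)), atol=1e-14)

    def test_null_binary_effect(self):
        state = ParameterState(
            ilr_intercept=np.array([0.3]),
            fixed_categorical={"Sex": np.zeros((1, 1))},
        )
        p = individual_proportions(state, EffectDesign(fixed_categorical=("Sex",)), self._mixture())
        assert np.allclose(p, p[0])

    def test_continuous_effect_monotone(self):
        state = ParameterState(
            ilr_intercept=np.array([0.0]),
            fixed_continuous={"Length": np.array([0.8])},
        )
        p = individual_proportions(
            state, EffectDesign(fixed_continuous=("Length",)), self._mixture()
        )
        assert np.all(np.diff(p[:, 0]) > 0)  # monotone in the ILR coordinate
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_collapses_to_global_model(self):
        state = ParameterState(
            ilr_intercept=np.array([0.5]),
            fixed_categorical={"Sex": np.zeros((1, 1))},
            fixed_continuous={"Length": np.zeros(1)},
        )
        p = individual_proportions(
            state,
            EffectDesign(fixed_categorical=("Sex",), fixed_continuous=("Length",)),
            self._mixture(),
        )
        np.testing.assert_allclose(p, np.tile(p[0], (p.shape[0], 1)), atol=1e-14)


class TestMixtureMoments:
    def test_vertex_mean(self):
        p = np.array([1.0, 0.0])
        mu = np.array([[-20.0, 5.0], [-10.0, 9.0]])
        np.testing.assert_allclose(mixture_mean(p, mu), [-20.0, 5.0])

    def test_hand_mean_with_discrimination(self):
        out = mixture_mean(
            np.array([0.5, 0.5]),
            np.array([[-20.0], [-10.0]]),
            discrimination_means=np.array([[1.0], [1.0]]),
        )
        assert out[0] == pytest.approx(-14.0)

    def test_equal_concentrations_cancel(self):
        p = np.array([0.3, 0.7])
        mu = np.array([[-20.0, 5.0], [-10.0, 9.0]])
        conc = np.full((2, 2), 0.42)
        np.testing.assert_allclose(mixture_mean(p, mu, concentrations=conc), mixture_mean(p, mu))

    def test_hand_variance(self):
        state = ParameterState(ilr_intercept=np.zeros(1), xi=np.array([2.0]))
        var = mixture_scale(
            np.array([0.5, 0.5]),
            np.array([[4.0], [8.0]]),
            None,
            state,
            ErrorSpec("process_x_multiplicative"),
        )
        assert var[0] == pytest.approx(6.0)

    def test_xi_one_equals_process_only(self):
        p = np.array([0.4, 0.6])
        w2 = np.array([[4.0, 2.0], [8.0, 3.0]])
        tau = np.array([[0.5, 0.1], [0.2, 0.3]])
        s1 = ParameterState(ilr_intercept=np.zeros(1), xi=np.ones(2))
        s2 = ParameterState(ilr_intercept=np.zeros(1))
        v1 = mixture_scale(p, w2, tau, s1, ErrorSpec("process_x_multiplicative"))
        v2 = mixture_scale(p, w2, tau, s2, ErrorSpec("process_only"))
        np.testing.assert_allclose(v1, v2, atol=1e-14)

    def test_vertex_variance(self):
        state = ParameterState(ilr_intercept=np.zeros(1), xi=np.array([3.0]))
        var = mixture_scale(
            np.array([1.0, 0.0]),
            np.array([[4.0], [9.0]]),
            np.zeros((2, 1)),
            state,
            ErrorSpec("process_x_multiplicative"),
        )
        assert var[0] == pytest.approx(12.0)

    def test_residual_independent_of_p(self):
        state = ParameterState(ilr_intercept=np.zeros(1), residual_sd=np.array([1.5]))
        for p1 in (0.1, 0.5, 0.9):
            var = mixture_scale(
                np.array([p1, 1 - p1]),
                np.array([[4.0], [9.0]]),
                None,
                state,
                ErrorSpec("residual_only"),
            )
            assert var[0] == pytest.approx(2.25)

    def test_diagonal_covariance_equals_independent(self):
        p = np.array([0.35, 0.65])
        sds = np.array([[1.0, 2.0], [1.5, 0.5]])
        covs = np.zeros((2, 2, 2))
        covs[:, 0, 0] = sds[:, 0] ** 2
        covs[:, 1, 1] = sds[:, 1] ** 2
        state = ParameterState(ilr_intercept=np.zeros(1), xi=np.array([1.3, 0.7]))
        v_ind = mixture_scale(p, sds**2, None, state, ErrorSpec("process_x_multiplicative"))
        v_cov = mixture_scale(
            p, sds**2, None, state, ErrorSpec("process_x_multiplicative"), source_covs=covs
        )
        np.testing.assert_allclose(np.diagonal(v_cov, axis1=-2, axis2=-1), v_ind, atol=1e-12)
        assert v_cov[0, 1] == pytest.approx(0.0)

    def test_variance_positive_property(self):
        rng = np.random.default_rng(0)
        state = ParameterState(ilr_intercept=np.zeros(2), xi=np.array([0.2, 5.0]))
        for _ in range(200):
            p = rng.dirichlet(np.ones(3))
            w2 = rng.uniform(0.1, 5, size=(3, 2))
            var = mixture_scale(p, w2, None, state, ErrorSpec("process_x_multiplicative"))
            assert np.all(var > 0)


class TestLogLikelihood:
    def test_single_point_at_mean(self):
        ds = make_fixed_dataset([[-15.0]], [[-20.0], [-10.0]], [[1.0], [1.0]])
        spec = ModelSpec(error=ErrorSpec("process_only"), source_treatment="fixed")
        state = ParameterState(ilr_intercept=np.zeros(1))
        # p = (0.5, 0.5) -> mean -15 exactly; var = 0.25+0.25 = 0.5
        res = log_likelihood_pointwise(state, spec, ds.mixture, ds.sources, ds.discrimination)
        assert res.mixture[0] == pytest.approx(-0.5 * np.log(2 * np.pi * 0.5))
        assert res.source == 0.0

    def test_fixed_vs_summary_state_mixture_terms_agree(self):
        y = np.random.default_rng(1).normal(-15, 1, size=(8, 1))
        ds_fixed = make_fixed_dataset(y, [[-20.0], [-10.0]], [[1.0], [1.5]])
        src_sum = make_summary_sources([[-20.0], [-10.0]], [[1.0], [1.5]], n=1_000_000)
        ds_sum = TracerDataset(mixture=ds_fixed.mixture, sources=src_sum)
        state_fixed = ParameterState(ilr_intercept=np.array([0.2]), xi=np.array([1.4]))
        state_sum = ParameterState(
            ilr_intercept=np.array([0.2]),
            xi=np.array([1.4]),
            source_means=src_sum.means.copy(),
            source_sds=src_sum.sds.copy(),
        )
        spec_f = ModelSpec(error=ErrorSpec("process_x_multiplicative"), source_treatment="fixed")
        spec_s = ModelSpec(error=ErrorSpec("process_x_multiplicative"), source_treatment="summary")
        ll_f = log_likelihood_pointwise(state_fixed, spec_f, ds_fixed.mixture, ds_fixed.sources, ds_fixed.discrimination)
        ll_s = log_likelihood_pointwise(state_sum, spec_s, ds_sum.mixture, ds_sum.sources, ds_sum.discrimination)
        np.testing.assert_allclose(ll_f.mixture, ll_s.mixture, atol=1e-3)

    def test_xi_doubling_analytic(self):
        y = np.array([[-19.0]])
        ds = make_fixed_dataset(y, [[-20.0], [-10.0]], [[2.0], [1.0]])
        spec = ModelSpec(error=ErrorSpec("process_x_multiplicative"), source_treatment="fixed")
        # vertex p=(1,0): z very large in coordinate 0
        state1 = ParameterState(ilr_intercept=np.array([30.0]), xi=np.array([1.0]))
        state2 = ParameterState(ilr_intercept=np.array([30.0]), xi=np.array([2.0]))
        ll1 = log_likelihood_pointwise(state1, spec, ds.mixture, ds.sources, ds.discrimination).mixture[0]
        ll2 = log_likelihood_pointwise(state2, spec, ds.mixture, ds.sources, ds.discrimination).mixture[0]
        # var 4 -> 8 at residual (y-mu) = 1
        expected = (-0.5 * (np.log(2 * np.pi * 8) + 1 / 8)) - (-0.5 * (np.log(2 * np.pi * 4) + 1 / 4))
        assert ll2 - ll1 == pytest.approx(expected, abs=1e-10)

    def test_residual_only_invariant_to_source_variances(self):
        y = np.random.default_rng(2).normal(-15, 1, size=(6, 1))
        spec = ModelSpec(error=ErrorSpec("residual_only"), source_treatment="fixed")
        state = ParameterState(ilr_intercept=np.array([0.1]), residual_sd=np.array([1.2]))
        lls = []
        for sds in ([[0.5], [0.5]], [[3.0], [4.0]]):
            ds = make_fixed_dataset(y, [[-20.0], [-10.0]], sds)
            lls.append(
                log_likelihood_pointwise(state, spec, ds.mixture, ds.sources, ds.discrimination).mixture
            )
        np.testing.assert_allclose(lls[0], lls[1], atol=1e-14)


class TestSpecs:
    def test_error_kind_validated(self):
        with pytest.raises(ValueError):
            ErrorSpec("additive")

    def test_process_only_requires_single_row(self):
        with pytest.raises(ValueError, match="single mixture row"):
            ErrorSpec("process_only").validate_for(5)

    def test_single_row_requires_process_only(self):
        with pytest.raises(ValueError):
            ErrorSpec("residual_only").validate_for(1)

    def test_covariance_requires_raw(self):
        with pytest.raises(ValueError, match="raw"):
            ModelSpec(source_treatment="summary", use_covariance=True)

    def test_factor_role_exclusive(self):
        with pytest.raises(ValueError, match="one role"):
            EffectDesign(fixed_categorical=("Sex",), random=("Sex",))

    def test_config_roundtrip(self):
        spec = ModelSpec(
            error=ErrorSpec("residual_only"),
            effects=EffectDesign(fixed_continuous=("Length",)),
            prior=DirichletPrior(np.array([2.0, 1.0])),
        )
        back = ModelSpec.from_dict(spec.to_dict())
        assert back.error.kind == "residual_only"
        assert back.effects.fixed_continuous == ("Length",)
        np.testing.assert_array_equal(back.prior.alpha, [2.0, 1.0])

    def test_two_level_random_effect_rejected(self, toy_fixed_dataset):
        ds = toy_fixed_dataset
        ds.mixture.fixed_factors = [
            Factor("Sex", np.tile([0, 1], 5), ["F", "M"])
        ]
        spec = ModelSpec(
            error=ErrorSpec("process_x_multiplicative"),
            effects=EffectDesign(random=("Sex",)),
            source_treatment="fixed",
        )
        with pytest.raises(ValueError, match="two groups"):
            spec.validate_for(ds)

    def test_concentration_flag_requires_table(self, toy_fixed_dataset):
        spec = ModelSpec(source_treatment="fixed", use_concentration=True)
        with pytest.raises(ValueError, match="concentration"):
            spec.validate_for(toy_fixed_dataset)
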