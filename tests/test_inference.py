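import numpy as np
import pytest
from scipy import stats

from isomix.inference import (
    McmcSettings,
    PosteriorDraws,
    convergence_diagnostics,
    fit,
    grid_posterior,
    posterior_summary,
    total_variation,
)
from isomix.io import as_fixed_sources
from isomix.model import EffectDesign, ErrorSpec, ModelSpec, TracerDataset, inverse_ilr
from isomix.priors import DirichletPrior
from isomix.simulate import SimulationScenario, simulate_bundle

from conftest import make_fixed_dataset


def _fast_settings(seed=0, n_chains=2, n_iter=3000):
    return McmcSettings(n_chains=n_chains, n_iter=n_iter, n_burn=n_iter // 2, thin=1, seed=seed)


def _fake_draws(x, p1=None, n_chains=4):
    """Wrap scalar draws (C, S) into a minimal PosteriorDraws."""
    c, s = x.shape
    if p1 is None:
        p1 = np.full((c, s), 0.5)
    p = np.stack([p1, 1 - p1], axis=-1)
    return PosteriorDraws(
        params={"x": x},
        p_global=p,
        loglik=np.zeros((c, s, 1)),
        source_names=["a", "b"],
        tracer_names=["t"],
    )


class TestSettings:
    def test_validation(self):
        with pytest.raises(ValueError):
            McmcSettings(n_iter=100, n_burn=100)
        with pytest.raises(ValueError):
            McmcSettings(thin=0)

    def test_presets(self):
        s = McmcSettings.preset("normal", seed=3)
        assert s.n_iter > s.n_burn and s.seed == 3
        with pytest.raises(ValueError):
            McmcSettings.preset("enormous")


class TestFit:
    def test_seed_determinism(self, toy_fixed_dataset):
        spec = ModelSpec(error=ErrorSpec("process_x_multiplicative"), source_treatment="fixed")
        a = fit(spec, toy_fixed_dataset, _fast_settings(seed=11, n_iter=600))
        b = fit(spec, toy_fixed_dataset, _fast_settings(seed=11, n_iter=600))
        np.testing.assert_array_equal(a.p_global, b.p_global)
        np.testing.assert_array_equal(a.loglik, b.loglik)
        c = fit(spec, toy_fixed_dataset, _fast_settings(seed=12, n_iter=600))
        assert not np.array_equal(a.p_global, c.p_global)

    def test_recovers_truth_within_3sd(self):
        scen = SimulationScenario(
            n_consumers=120,
            source_means=np.array([[-20.0, 2.0], [-8.0, 12.0]]),
            source_sds=np.array([[1.0, 1.0], [1.0, 1.0]]),
            p_global=np.array([0.7, 0.3]),
            error=ErrorSpec("residual_only"),
            sigma=np.array([1.0, 1.0]),
            seed=5,
        )
        ds, truth = simulate_bundle(scen, source_mode="summary")
        ds = TracerDataset(ds.mixture, as_fixed_sources(ds.sources), ds.discrimination)
        spec = ModelSpec(error=ErrorSpec("residual_only"), source_treatment="fixed")
        draws = fit(spec, ds, _fast_settings(seed=1, n_iter=4000))
        p1 = draws.p_global[:, :, 0].reshape(-1)
        assert abs(p1.mean() - truth["p_global"][0]) < 3 * p1.std(ddof=1) + 0.02

    def test_single_row_auto_process_only(self):
        ds = make_fixed_dataset([[-15.0]], [[-20.0], [-10.0]], [[1.0], [1.0]])
        spec = ModelSpec(error=ErrorSpec("process_x_multiplicative"), source_treatment="fixed")
        with pytest.warns(UserWarning, match="process_only"):
            draws = fit(spec, ds, _fast_settings(seed=0, n_iter=500))
        assert draws.meta["model"]["error"] == "process_only"
        assert "xi" not in draws.params

    def test_prior_recovery_prior_only(self, toy_fixed_dataset):
        # likelihood disabled: p marginals must match the Dirichlet prior
        spec = ModelSpec(
            error=ErrorSpec("process_x_multiplicative"),
            source_treatment="fixed",
            prior=DirichletPrior(np.array([1.0, 1.0])),
        )
        settings = McmcSettings(n_chains=3, n_iter=40_000, n_burn=4_000, thin=2, seed=8)
        draws = fit(spec, toy_fixed_dataset, settings, prior_only=True)
        p1 = draws.p_global[:, :, 0].reshape(-1)
        # adjust the KS test for autocorrelation via an effective sample size
        n_eff = _ess(draws.p_global[:, :, 0])
        d_stat = stats.kstest(p1, "uniform").statistic
        assert d_stat < 1.628 / np.sqrt(n_eff)  # alpha = 0.01

    def test_loglik_matrix_retained(self, toy_fixed_dataset):
        spec = ModelSpec(error=ErrorSpec("process_x_multiplicative"), source_treatment="fixed")
        draws = fit(spec, toy_fixed_dataset, _fast_settings(seed=2, n_iter=600))
        assert draws.loglik.shape[2] == toy_fixed_dataset.mixture.n
        assert np.all(np.isfinite(draws.loglik))


def _ess(x):
    """Effective sample size across chains (initial positive sequence)."""
    c, s = x.shape
    total = 0.0
    for ch in range(c):
        v = x[ch] - x[ch].mean()
        acf = np.correlate(v, v, mode="full")[s - 1 :] / (np.arange(s, 0, -1) * v.var())
        tau = 1.0
        for lag in range(1, min(s, 1000)):
            if acf[lag] <= 0:
                break
            tau += 2 * acf[lag]
        total += s / tau
    return total


class TestDiagnostics:
    def test_iid_normals_pass(self, rng):
        x = rng.standard_normal((4, 2000))
        df = convergence_diagnostics(_fake_draws(x))
        row = df[df.parameter == "x"].iloc[0]
        assert abs(row.rhat - 1.0) < 0.01
        assert row["pass"]

    def test_shifted_chains_flagged(self, rng):
        x = rng.standard_normal((2, 1000))
        x[1] += 5.0
        df = convergence_diagnostics(_fake_draws(x, n_chains=2))
        row = df[df.parameter == "x"].iloc[0]
        assert row.rhat > 1.5 and not row["pass"]

    def test_constant_parameter_degenerate(self):
        x = np.full((3, 500), 2.5)
        df = convergence_diagnostics(_fake_draws(x))
        row = df[df.parameter == "x"].iloc[0]
        assert row.degenerate and row["pass"]

    def test_single_chain_warns(self, rng):
        x = rng.standard_normal((1, 1000))
        with pytest.warns(UserWarning, match="2 chains"):
            df = convergence_diagnostics(_fake_draws(x))
        assert np.isnan(df[df.parameter == "x"].iloc[0].rhat)


class TestPosteriorSummary:
    def test_symmetric_mean_equals_median(self, rng):
        x = rng.standard_normal((2, 20_000))
        df = posterior_summary(_fake_draws(x))
        row = df[df.parameter == "x"].iloc[0]
        assert abs(row["mean"] - row["median"]) < 0.02

    def test_uniform_interval(self, rng):
        x = rng.uniform(size=(2, 50_000))
        df = posterior_summary(_fake_draws(x))
        row = df[df.parameter == "x"].iloc[0]
        assert row["q0.025"] == pytest.approx(0.025, abs=0.005)
        assert row["q0.975"] == pytest.approx(0.975, abs=0.005)

    def test_includes_epsilon(self, rng):
        x = rng.standard_normal((2, 100))
        df = posterior_summary(_fake_draws(x))
        assert "epsilon(p_global)" in set(df.parameter)


class TestGridPosterior:
    def test_flat_likelihood_returns_prior(self):
        # identical sources + residual error: likelihood carries no
        # information about p (mean and variance both p-free)
        y = np.random.default_rng(0).normal(-15, 1, size=(10, 1))
        ds = make_fixed_dataset(y, [[-15.0], [-15.0]], [[1.0], [1.0]])
        spec = ModelSpec(
            error=ErrorSpec("residual_only"),
            source_treatment="fixed",
            prior=DirichletPrior(np.array([2.0, 5.0])),
        )
        g, pmf = grid_posterior(spec, ds, 500)
        prior_pdf = stats.beta(2, 5).pdf(g)
        np.testing.assert_allclose(pmf, prior_pdf / prior_pdf.sum(), atol=1e-6)

    def test_vertex_recovery(self):
        rng = np.random.default_rng(1)
        y = rng.normal(-20.0, 0.5, size=(20, 1))
        ds = make_fixed_dataset(y, [[-20.0], [-5.0]], [[0.5], [0.5]])
        spec = ModelSpec(error=ErrorSpec("process_x_multiplicative"), source_treatment="fixed")
        g, pmf = grid_posterior(spec, ds, 400)
        assert pmf[g > 0.9].sum() > 0.95

    def test_constraints(self, toy_fixed_dataset):
        spec = ModelSpec(error=ErrorSpec("process_x_multiplicative"), source_treatment="fixed")
        with pytest.raises(ValueError, match=">= 200"):
            grid_posterior(spec, toy_fixed_dataset, 50)
        ds3 = make_fixed_dataset(
            np.zeros((4, 1)), [[-20.0], [-10.0], [0.0]], [[1.0], [1.0], [1.0]]
        )
        with pytest.raises(ValueError, match="2 sources"):
            grid_posterior(spec, ds3, 400)


class TestPersistence:
    def test_roundtrip(self, tmp_path, toy_fixed_dataset):
        spec = ModelSpec(error=ErrorSpec("process_x_multiplicative"), source_treatment="fixed")
        draws = fit(spec, toy_fixed_dataset, _fast_settings(seed=4, n_iter=600))
        draws.to_dir(tmp_path / "archive")
        back = PosteriorDraws.from_dir(tmp_path / "archive")
        np.testing.assert_allclose(back.p_global, draws.p_global, atol=1e-15)
        np.testing.assert_allclose(back.loglik, draws.loglik, atol=1e-15)
        np.testing.assert_allclose(back.stacked("xi"), draws.stacked("xi"), atol=1e-15)
        assert back.meta["data_hash"] == draws.meta["data_hash"]
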