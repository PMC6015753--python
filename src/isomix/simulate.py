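"""Synthetic dataset generation with the exact statistical structure each
error structure and effect design assumes, so every stage is testable
without external data."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from isomix.io import (
    DiscriminationData,
    Factor,
    MixtureData,
    SourceData,
    zero_discrimination,
)
from isomix.model import (
    ErrorSpec,
    TracerDataset,
    ilr_basis,
    ilr_transform,
    inverse_ilr,
)

__all__ = [
    "ContinuousRule",
    "CategoricalRule",
    "RandomRule",
    "SimulationScenario",
    "simulate_sources",
    "simulate_mixture",
    "simulate_bundle",
    "alligator_like_fixture",
    "AlligatorLikeBundle",
]


@dataclass(frozen=True)
class ContinuousRule:
    """A continuous covariate: uniform on (low, high), ILR slope on the
    empirically standardized scale (so fitted slopes recover it directly)."""

    name: str
    low: float
    high: float
    slope: tuple[float, ...]  # (K-1,)


@dataclass(frozen=True)
class CategoricalRule:
    name: str
    levels: tuple[str, ...]
    coefficients: tuple[tuple[float, ...], ...]  # (L-1, K-1), level 0 = reference


@dataclass(frozen=True)
class RandomRule:
    name: str
    n_levels: int
    sd: float  # true gamma


@dataclass
class SimulationScenario:
    """Everything needed to generate a reproducible synthetic data bundle."""

    n_consumers: int
    source_means: np.ndarray  # (K, J)
    source_sds: np.ndarray  # (K, J)
    p_global: np.ndarray | None = None  # implies the ILR intercept
    ilr_intercept: np.ndarray | None = None
    continuous: tuple[ContinuousRule, ...] = ()
    categorical: tuple[CategoricalRule, ...] = ()
    random: tuple[RandomRule, ...] = ()
    error: ErrorSpec = field(default_factory=lambda: ErrorSpec("process_x_multiplicative"))
    sigma: np.ndarray | None = None  # (J,) residual SDs
    xi: np.ndarray | None = None  # (J,) multiplicative terms
    discrimination_means: np.ndarray | None = None
    discrimination_sds: np.ndarray | None = None
    concentrations: np.ndarray | None = None
    source_sample_sizes: np.ndarray | None = None  # default 25 each
    source_corr: np.ndarray | None = None  # (K,) tracer correlation (J=2)
    source_names: list[str] | None = None
    tracer_names: list[str] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.source_means = np.atleast_2d(np.asarray(self.source_means, dtype=float))
        self.source_sds = np.atleast_2d(np.asarray(self.source_sds, dtype=float))
        if np.any(self.source_sds < 0):
            raise ValueError("source SDs must be non-negative")
        k, j = self.source_means.shape
        if self.source_names is None:
            self.source_names = [f"source_{i + 1}" for i in range(k)]
        if self.tracer_names is None:
            self.tracer_names = [f"tracer_{i + 1}" for i in range(j)]
        if self.p_global is not None:
            p = np.asarray(self.p_global, dtype=float)
            if p.size != k or np.any(p <= 0) or abs(p.sum() - 1) > 1e-10:
                raise ValueError("p_global must be a strictly positive K-composition")
            self.ilr_intercept = ilr_transform(p)
        if self.ilr_intercept is None:
            raise ValueError("provide p_global or ilr_intercept")
        self.ilr_intercept = np.atleast_1d(np.asarray(self.ilr_intercept, dtype=float))
        if self.ilr_intercept.size != k - 1:
            raise ValueError("ilr_intercept must have length K-1")
        if self.error.kind == "residual_only" and self.sigma is None:
            raise ValueError("residual_only scenario needs sigma")
        if self.error.kind == "process_x_multiplicative" and self.xi is None:
            raise ValueError("multiplicative scenario needs xi")
        if self.source_sample_sizes is None:
            self.source_sample_sizes = np.full(k, 25)
        if self.discrimination_means is None:
            self.discrimination_means = np.zeros((k, j))
        if self.discrimination_sds is None:
            self.discrimination_sds = np.zeros((k, j))

    @property
    def n_sources(self) -> int:
        return self.source_means.shape[0]

    @property
    def n_tracers(self) -> int:
        return self.source_means.shape[1]

    def discrimination(self) -> DiscriminationData:
        return DiscriminationData(
            means=np.asarray(self.discrimination_means, dtype=float),
            sds=np.asarray(self.discrimination_sds, dtype=float),
        )


def _rng(scenario: SimulationScenario, seed: int | None) -> np.random.Generator:
    if seed is None:
        seed = scenario.seed
    return np.random.default_rng(seed)


def simulate_sources(
    scenario: SimulationScenario,
    seed: int | None = None,
    mode: str = "raw",
) -> SourceData:
    """Draw per-source samples from (multivariate) normals.

    ``mode='summary'`` returns the exact sample statistics of the drawn
    samples instead of the samples themselves.
    """
    if mode not in ("raw", "summary"):
        raise ValueError("mode must be 'raw' or 'summary'")
    rng = _rng(scenario, seed)
    k, j = scenario.n_sources, scenario.n_tracers
    samples = []
    for ki in range(k):
        n_k = int(scenario.source_sample_sizes[ki])
        mu = scenario.source_means[ki]
        sd = scenario.source_sds[ki]
        if scenario.source_corr is not None and j == 2:
            rho = float(scenario.source_corr[ki])
            cov = np.array(
                [
                    [sd[0] ** 2, rho * sd[0] * sd[1]],
                    [rho * sd[0] * sd[1], sd[1] ** 2],
                ]
            )
            samp = rng.multivariate_normal(mu, cov, size=n_k, method="cholesky")
        else:
            samp = mu + sd * rng.standard_normal((n_k, j))
        samples.append(samp)
    means = np.array([s.mean(axis=0) for s in samples])
    sds = np.array([s.std(axis=0, ddof=1) for s in samples])
    common = dict(
        source_names=list(scenario.source_names),
        means=means,
        sds=sds,
        sample_sizes=scenario.source_sample_sizes.copy(),
        tracer_names=list(scenario.tracer_names),
        concentrations=None
        if scenario.concentrations is None
        else np.asarray(scenario.concentrations, dtype=float),
    )
    if mode == "raw":
        return SourceData(treatment="raw", raw_samples=samples, **common)
    return SourceData(treatment="summary", **common)


def _simulate_covariates(
    scenario: SimulationScenario, rng: np.random.Generator
) -> tuple[np.ndarray, list[Factor], list[Factor], list[tuple[str, np.ndarray]], dict]:
    """Returns (z rows, fixed factors, random factors, continuous covs, truth)."""
    n = scenario.n_consumers
    km1 = scenario.n_sources - 1
    z = np.tile(scenario.ilr_intercept, (n, 1))
    fixed_factors: list[Factor] = []
    random_factors: list[Factor] = []
    continuous: list[tuple[str, np.ndarray]] = []
    truth: dict = {"ilr_intercept": scenario.ilr_intercept.copy()}

    for rule in scenario.categorical:
        codes = rng.integers(0, len(rule.levels), size=n)
        coefs = np.asarray(rule.coefficients, dtype=float).reshape(len(rule.levels) - 1, km1)
        full = np.vstack([np.zeros((1, km1)), coefs])
        z += full[codes]
        fixed_factors.append(Factor(rule.name, codes, list(rule.levels)))
        truth[f"coef:{rule.name}"] = coefs
    for rule in scenario.continuous:
        x = rng.uniform(rule.low, rule.high, size=n)
        xs = (x - x.mean()) / x.std(ddof=0)
        slope = np.asarray(rule.slope, dtype=float)
        z += xs[:, None] * slope[None, :]
        continuous.append((rule.name, x))
        truth[f"slope:{rule.name}"] = slope
    for rule in scenario.random:
        offsets = rule.sd * rng.standard_normal((rule.n_levels, km1))
        codes = (
            np.arange(n) % rule.n_levels
            if rule.n_levels >= n
            else rng.integers(0, rule.n_levels, size=n)
        )
        z += offsets[codes]
        random_factors.append(
            Factor(rule.name, codes, [f"{rule.name}_{i + 1}" for i in range(rule.n_levels)])
        )
        truth[f"offsets:{rule.name}"] = offsets
        truth[f"gamma:{rule.name}"] = rule.sd
    return z, fixed_factors, random_factors, continuous, truth


def simulate_mixture(
    scenario: SimulationScenario,
    source_truth: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[MixtureData, dict]:
    """Generate consumers under the scenario's error structure.

    ``source_truth`` overrides the source means used in the mixing
    equation (defaults to the scenario's true means).  Returns the
    mixture plus a record of the underlying truth (per-individual p,
    ILR parameters).
    """
    rng = _rng(scenario, seed)
    z, fixed_factors, random_factors, continuous, truth = _simulate_covariates(scenario, rng)
    p = inverse_ilr(z)  # (N, K)
    mu = (source_truth if source_truth is not None else scenario.source_means) + np.asarray(
        scenario.discrimination_means, dtype=float
    )

    if scenario.concentrations is not None:
        conc = np.asarray(scenario.concentrations, dtype=float)
        num = p[:, :, None] * conc
        q = num / num.sum(axis=1, keepdims=True)
        mean = (q * mu).sum(axis=1)
        w2 = q**2
    else:
        mean = p @ mu
        w2 = (p**2)[:, :, None]

    if scenario.error.kind == "residual_only":
        var = np.broadcast_to(np.asarray(scenario.sigma, dtype=float) ** 2, mean.shape)
    else:
        pvar = scenario.source_sds**2 + np.asarray(scenario.discrimination_sds, dtype=float) ** 2
        var = (w2 * pvar).sum(axis=1)
        if scenario.error.kind == "process_x_multiplicative":
            var = var * np.asarray(scenario.xi, dtype=float)[None, :]

    y = mean + np.sqrt(var) * rng.standard_normal(mean.shape)
    mixture = MixtureData(
        values=y,
        tracer_names=list(scenario.tracer_names),
        fixed_factors=fixed_factors,
        random_factors=random_factors,
        continuous_covariates=continuous,
    )
    truth["p_individual"] = p
    truth["p_global"] = inverse_ilr(scenario.ilr_intercept)
    if scenario.xi is not None:
        truth["xi"] = np.asarray(scenario.xi, dtype=float)
    if scenario.sigma is not None:
        truth["sigma"] = np.asarray(scenario.sigma, dtype=float)
    return mixture, truth


def simulate_bundle(
    scenario: SimulationScenario,
    seed: int | None = None,
    source_mode: str = "summary",
) -> tuple[TracerDataset, dict]:
    """Sources + mixture + discrimination as one dataset, with the truth record.

    Seed determinism: identical scenario and seed give bit-identical
    bundles.
    """
    base = scenario.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    s_src, s_mix = ss.spawn(2)
    sources = simulate_sources(scenario, seed=s_src, mode=source_mode)
    # feed the *true* means into the mixing equation, not the sampled ones
    mixture, truth = simulate_mixture(scenario, seed=s_mix)
    dataset = TracerDataset(
        mixture=mixture, sources=sources, discrimination=scenario.discrimination()
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# the 2-source / 2-tracer case-study-shaped fixture
# ---------------------------------------------------------------------------


@dataclass
class AlligatorLikeBundle:
    """A 181-consumer, 2-source, 2-tracer bundle with known truth."""

    dataset: TracerDataset
    scenario: SimulationScenario
    truth: dict

    def true_p_marine(self, length: np.ndarray | float) -> np.ndarray | float:
        """True marine proportion at raw-scale length values."""
        lengths = self.dataset.mixture.covariate("Length")
        xs = (np.asarray(length, dtype=float) - lengths.mean()) / lengths.std(ddof=0)
        slope = self.truth["slope:Length"]
        z = self.truth["ilr_intercept"] + np.atleast_1d(xs)[:, None] * slope[None, :]
        p = inverse_ilr(z)[:, 1]
        return float(p[0]) if np.isscalar(length) else p


def alligator_like_fixture(seed: int = 0, n_consumers: int = 181) -> AlligatorLikeBundle:
    """Synthetic bundle shaped like a freshwater/marine ontogenetic-diet
    study: 181 consumers, 2 sources, 2 isotope tracers, a continuous
    Length covariate driving the diet shift, Sex and Size-class factors,
    and an Individual factor for random-effect models."""
    scenario = SimulationScenario(
        n_consumers=n_consumers,
        source_means=np.array([[-27.0, 7.5], [-17.5, 11.0]]),
        source_sds=np.array([[1.6, 1.1], [1.3, 1.0]]),
        ilr_intercept=np.array([0.35]),
        continuous=(ContinuousRule("Length", 37.7, 315.5, slope=(-1.05,)),),
        error=ErrorSpec("process_x_multiplicative"),
        xi=np.array([5.0, 1.0]),
        discrimination_means=np.array([[0.4, 1.0], [0.4, 1.0]]),
        discrimination_sds=np.array([[0.2, 0.3], [0.2, 0.3]]),
        source_sample_sizes=np.array([30, 30]),
        source_names=["freshwater", "marine"],
        tracer_names=["d13C", "d15N"],
        seed=seed,
    )
    dataset, truth = simulate_bundle(scenario, seed=seed)
    mix = dataset.mixture
    lengths = mix.covariate("Length")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]).entropy)

    # Sex (balanced) and a length-derived size class, as in ontogenetic studies
    sex = Factor("Sex", rng.integers(0, 2, size=mix.n), ["female", "male"])
    edges = np.quantile(lengths, [0.25, 0.5, 0.75])
    size_codes = np.digitize(lengths, edges)
    size = Factor(
        "Size_class", size_codes, ["small_juvenile", "large_juvenile", "subadult", "adult"]
    )
    individual = Factor("Individual", np.arange(mix.n), [f"ind_{i}" for i in range(mix.n)])
    mix.fixed_factors = [sex, size]
    mix.random_factors = [individual]
    truth["sex_factor"] = sex
    truth["size_factor"] = size
    return AlligatorLikeBundle(dataset=dataset, scenario=scenario, truth=truth)
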