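"""Joint model definition: ILR-space linear predictors for per-individual
proportions, the mixture likelihood under three error structures, and the
source-data likelihood under three treatments.

Error structures for the mixture rows (per tracer j):

* ``residual_only``     Y_ij ~ N(sum_k p_k mu_jk, sigma_j^2)
* ``process_only``      Y_ij ~ N(sum_k p_k mu_jk, sum_k p_k^2 omega_jk^2)
  (only valid for a single mixture row, where no residual variance is
  estimable)
* ``process_x_multiplicative``
                        Y_ij ~ N(sum_k p_k mu_jk, xi_j * sum_k p_k^2 omega_jk^2)

Discrimination shifts are added to the source means and their SDs enter
the process variance additively (omega^2 + tau^2).  Concentration
dependence uses the mass-balance ratio form: the effective weight of
source k for tracer j is p_k c_jk / sum_k p_k c_jk.

The ILR basis is a fixed Egozcue-style sequential binary partition in
source-input order (coordinate r balances part r against parts r+1..K).
Posterior proportions are basis-invariant; ILR-space coefficients are
reported relative to this basis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from isomix.io import DiscriminationData, MixtureData, SourceData, zero_discrimination
from isomix.priors import DirichletPrior, VariancePriorSpec

__all__ = [
    "ErrorSpec",
    "EffectDesign",
    "ModelSpec",
    "ParameterState",
    "TracerDataset",
    "DesignInfo",
    "ilr_basis",
    "ilr_transform",
    "inverse_ilr",
    "ilr_dirichlet_logpdf",
    "build_design",
    "individual_proportions",
    "mixture_mean",
    "mixture_scale",
    "log_likelihood_pointwise",
]

ERROR_KINDS = ("residual_only", "process_only", "process_x_multiplicative")


# ---------------------------------------------------------------------------
# ILR transform
# ---------------------------------------------------------------------------


def ilr_basis(n_parts: int) -> np.ndarray:
    """Orthonormal (K, K-1) contrast matrix V with V.T @ 1 = 0.

    Column r is the balance of part r against parts r+1..K:
    V[r, r] = sqrt(a/(a+1)), V[r+1:, r] = -1/sqrt(a(a+1)) with
    a = K - r - 1.
    """
    if n_parts < 2:
        raise ValueError("ILR needs at least 2 parts")
    k = n_parts
    v = np.zeros((k, k - 1))
    for r in range(k - 1):
        a = k - r - 1
        v[r, r] = np.sqrt(a / (a + 1.0))
        v[r + 1 :, r] = -1.0 / np.sqrt(a * (a + 1.0))
    return v


def ilr_transform(p: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Map compositions (..., K) on the open simplex to (..., K-1) coordinates."""
    p = np.asarray(p, dtype=float)
    k = p.shape[-1]
    if np.any(p <= 0):
        raise ValueError("boundary compositions (p_k <= 0) have no ILR image")
    if np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-10):
        raise ValueError("compositions must sum to 1 (tolerance 1e-10)")
    v = ilr_basis(k) if basis is None else basis
    return np.log(p) @ v


def inverse_ilr(z: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Map (..., K-1) ILR coordinates back to strictly positive compositions."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("ILR coordinates must be finite")
    if z.ndim == 0:
        z = z[None]
    km1 = z.shape[-1]
    v = ilr_basis(km1 + 1) if basis is None else basis
    y = z @ v.T
    y -= y.max(axis=-1, keepdims=True)  # overflow-safe softmax
    ey = np.exp(y)
    return ey / ey.sum(axis=-1, keepdims=True)


def ilr_dirichlet_logpdf(z: np.ndarray, alpha: np.ndarray) -> float | np.ndarray:
    """Log density in ILR space induced by a Dirichlet(alpha) prior on p.

    The change of variables contributes log(sqrt(K)) + sum_k log p_k.
    """
    alpha = np.asarray(alpha, dtype=float)
    k = alpha.size
    p = inverse_ilr(z)
    logp = np.log(p)
    log_dir = (
        gammaln(alpha.sum())
        - gammaln(alpha).sum()
        + ((alpha - 1.0) * logp).sum(axis=-1)
    )
    return log_dir + 0.5 * np.log(k) + logp.sum(axis=-1)


# ---------------------------------------------------------------------------
# specification types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErrorSpec:
    """Which mixture error structure to use."""

    kind: str = "process_x_multiplicative"

    def __post_init__(self) -> None:
        if self.kind not in ERROR_KINDS:
            raise ValueError(f"error kind must be one of {ERROR_KINDS}, got {self.kind!r}")

    def validate_for(self, n_mixture_rows: int) -> None:
        if self.kind == "process_only" and n_mixture_rows > 1:
            raise ValueError(
                "process_only error is permitted only for a single mixture row; "
                "use process_x_multiplicative or residual_only"
            )
        if self.kind != "process_only" and n_mixture_rows == 1:
            raise ValueError(
                "a single mixture row cannot identify a residual/multiplicative "
                "variance term; use process_only"
            )


@dataclass(frozen=True)
class EffectDesign:
    """Which covariates enter the ILR-space linear predictor, and how."""

    fixed_categorical: tuple[str, ...] = ()
    fixed_continuous: tuple[str, ...] = ()
    random: tuple[str, ...] = ()
    include_intercept: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_categorical", tuple(self.fixed_categorical))
        object.__setattr__(self, "fixed_continuous", tuple(self.fixed_continuous))
        object.__setattr__(self, "random", tuple(self.random))
        if not self.include_intercept:
            raise ValueError("the intercept is always included")
        names = list(self.fixed_categorical) + list(self.fixed_continuous) + list(self.random)
        if len(set(names)) != len(names):
            raise ValueError("a covariate may appear in at most one role")

    @property
    def is_intercept_only(self) -> bool:
        return not (self.fixed_categorical or self.fixed_continuous or self.random)


@dataclass
class ModelSpec:
    """Error structure + effect design + priors: fully determines the joint density."""

    error: ErrorSpec = field(default_factory=ErrorSpec)
    effects: EffectDesign = field(default_factory=EffectDesign)
    prior: DirichletPrior | None = None
    variance_priors: VariancePriorSpec = field(default_factory=VariancePriorSpec)
    source_treatment: str = "summary"
    use_covariance: bool = False
    use_concentration: bool = False

    def __post_init__(self) -> None:
        if self.source_treatment not in ("raw", "summary", "fixed"):
            raise ValueError(f"unknown source treatment {self.source_treatment!r}")
        if self.use_covariance and self.source_treatment != "raw":
            raise ValueError("use_covariance requires raw source data")

    def validate_for(self, dataset: "TracerDataset") -> None:
        self.error.validate_for(dataset.mixture.n)
        if self.source_treatment != dataset.sources.treatment:
            raise ValueError(
                f"model source_treatment {self.source_treatment!r} does not match "
                f"data treatment {dataset.sources.treatment!r}"
            )
        if self.use_concentration and dataset.sources.concentrations is None:
            raise ValueError("use_concentration requires a concentration table")
        if self.prior is not None and self.prior.n_sources != dataset.sources.n_sources:
            raise ValueError("Dirichlet prior length does not match number of sources")
        mix = dataset.mixture
        for name in self.effects.fixed_categorical:
            mix.factor(name)
        for name in self.effects.fixed_continuous:
            mix.covariate(name)
        for name in self.effects.random:
            fac = mix.factor(name)
            if fac.n_levels == 2:
                raise ValueError(
                    f"factor {name!r} has only two groups; use a fixed effect"
                )

    # -- config round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        vp = self.variance_priors
        return {
            "error": self.error.kind,
            "effects": {
                "fixed_categorical": list(self.effects.fixed_categorical),
                "fixed_continuous": list(self.effects.fixed_continuous),
                "random": list(self.effects.random),
            },
            "prior_alpha": None if self.prior is None else self.prior.alpha.tolist(),
            "variance_priors": {
                "residual_sd_upper": vp.residual_sd_upper,
                "multiplicative_xi_prior": list(vp.multiplicative_xi_prior),
                "random_effect_sd_upper": vp.random_effect_sd_upper,
                "ilr_coefficient_sd": vp.ilr_coefficient_sd,
                "source_mean_prior_sd": vp.source_mean_prior_sd,
            },
            "source_treatment": self.source_treatment,
            "use_covariance": self.use_covariance,
            "use_concentration": self.use_concentration,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        vp_d = dict(d.get("variance_priors", {}))
        if "multiplicative_xi_prior" in vp_d:
            fam, par = vp_d["multiplicative_xi_prior"]
            vp_d["multiplicative_xi_prior"] = (str(fam), float(par))
        eff = d.get("effects", {})
        prior_alpha = d.get("prior_alpha")
        return cls(
            error=ErrorSpec(d.get("error", "process_x_multiplicative")),
            effects=EffectDesign(
                fixed_categorical=tuple(eff.get("fixed_categorical", ())),
                fixed_continuous=tuple(eff.get("fixed_continuous", ())),
                random=tuple(eff.get("random", ())),
            ),
            prior=None if prior_alpha is None else DirichletPrior(np.asarray(prior_alpha)),
            variance_priors=VariancePriorSpec(**vp_d),
            source_treatment=d.get("source_treatment", "summary"),
            use_covariance=bool(d.get("use_covariance", False)),
            use_concentration=bool(d.get("use_concentration", False)),
        )


@dataclass
class TracerDataset:
    """Bundle of mixture, source, and discrimination data with matched shapes."""

    mixture: MixtureData
    sources: SourceData
    discrimination: DiscriminationData | None = None

    def __post_init__(self) -> None:
        if self.mixture.n_tracers != self.sources.n_tracers:
            raise ValueError("mixture and source tracer counts differ")
        if self.discrimination is None:
            self.discrimination = zero_discrimination(
                self.sources.n_sources, self.sources.n_tracers
            )
        if self.discrimination.means.shape != self.sources.means.shape:
            raise ValueError("discrimination shape does not match sources")

    @property
    def n_sources(self) -> int:
        return self.sources.n_sources

    @property
    def n_tracers(self) -> int:
        return self.sources.n_tracers

    def data_hash(self) -> str:
        """Hash of the mixture observations (model-comparison guard)."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.mixture.values).tobytes())
        return h.hexdigest()[:16]


@dataclass
class ParameterState:
    """One point in parameter space.

    ``fixed_categorical`` holds (L-1, K-1) coefficient matrices
    (reference coding: level 0 is the baseline); ``fixed_continuous``
    holds (K-1,) slope vectors on the standardized covariate scale;
    ``random_offsets`` holds (L, K-1) per-level offsets with one SD per
    factor.  ``source_covs`` (K, J, J), when set, replaces the
    independent-tracer variances.
    """

    ilr_intercept: np.ndarray
    fixed_categorical: dict[str, np.ndarray] = field(default_factory=dict)
    fixed_continuous: dict[str, np.ndarray] = field(default_factory=dict)
    random_offsets: dict[str, np.ndarray] = field(default_factory=dict)
    random_sds: dict[str, float] = field(default_factory=dict)
    residual_sd: np.ndarray | None = None
    xi: np.ndarray | None = None
    source_means: np.ndarray | None = None
    source_sds: np.ndarray | None = None
    source_covs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ilr_intercept = np.atleast_1d(np.asarray(self.ilr_intercept, dtype=float))
        if self.residual_sd is not None:
            self.residual_sd = np.atleast_1d(np.asarray(self.residual_sd, dtype=float))
            if np.any(self.residual_sd <= 0):
                raise ValueError("residual_sd must be > 0")
        if self.xi is not None:
            self.xi = np.atleast_1d(np.asarray(self.xi, dtype=float))
            if np.any(self.xi <= 0):
                raise ValueError("xi must be > 0")


# ---------------------------------------------------------------------------
# design info / per-individual proportions
# ---------------------------------------------------------------------------


@dataclass
class DesignInfo:
    """Frozen covariate bookkeeping: level maps and standardization constants.

    Continuous covariates are centered and scaled to unit SD internally
    (sampler geometry); the stored constants let predictions accept
    raw-scale values.
    """

    effects: EffectDesign
    factor_levels: dict[str, list[str]]
    covariate_center: dict[str, float]
    covariate_scale: dict[str, float]
    covariate_range: dict[str, tuple[float, float]]

    def standardize(self, name: str, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.covariate_center[name]) / self.covariate_scale[name]

    def level_codes(self, name: str, labels: Sequence[str]) -> np.ndarray:
        levels = self.factor_levels[name]
        codes = np.empty(len(labels), dtype=int)
        for i, lab in enumerate(labels):
            if str(lab) not in levels:
                raise ValueError(
                    f"factor {name!r}: level {lab!r} was not observed at fit time"
                )
            codes[i] = levels.index(str(lab))
        return codes


def build_design(effects: EffectDesign, mixture: MixtureData) -> DesignInfo:
    factor_levels: dict[str, list[str]] = {}
    for name in list(effects.fixed_categorical) + list(effects.random):
        factor_levels[name] = list(mixture.factor(name).levels)
    center, scale, rng = {}, {}, {}
    for name in effects.fixed_continuous:
        vals = mixture.covariate(name)
        center[name] = float(vals.mean())
        s = float(vals.std(ddof=0))
        scale[name] = s if s > 0 else 1.0
        rng[name] = (float(vals.min()), float(vals.max()))
    return DesignInfo(
        effects=effects,
        factor_levels=factor_levels,
        covariate_center=center,
        covariate_scale=scale,
        covariate_range=rng,
    )


def linear_predictor(
    state: ParameterState,
    design: DesignInfo,
    factor_codes: Mapping[str, np.ndarray],
    covariate_values: Mapping[str, np.ndarray],
    n_rows: int,
) -> np.ndarray:
    """ILR-space predictor z_i = beta0 + sum(fixed terms) + sum(random offsets)."""
    z = np.broadcast_to(state.ilr_intercept, (n_rows, state.ilr_intercept.size)).copy()
    for name in design.effects.fixed_categorical:
        codes = factor_codes[name]
        coef = state.fixed_categorical[name]  # (L-1, K-1)
        full = np.vstack([np.zeros((1, coef.shape[1])), coef])
        z += full[codes]
    for name in design.effects.fixed_continuous:
        x = design.standardize(name, covariate_values[name])
        z += np.outer(x, state.fixed_continuous[name])
    for name in design.effects.random:
        codes = factor_codes[name]
        z += state.random_offsets[name][codes]
    return z


def individual_proportions(
    state: ParameterState,
    effects: EffectDesign,
    mixture: MixtureData,
    design: DesignInfo | None = None,
) -> np.ndarray:
    """Per-individual proportions: rows are inverse_ilr of the linear predictor."""
    if design is None:
        design = build_design(effects, mixture)
    factor_codes = {
        name: mixture.factor(name).codes
        for name in list(effects.fixed_categorical) + list(effects.random)
    }
    covars = {name: mixture.covariate(name) for name in effects.fixed_continuous}
    z = linear_predictor(state, design, factor_codes, covars, mixture.n)
    return inverse_ilr(z)


# ---------------------------------------------------------------------------
# mixture moments
# ---------------------------------------------------------------------------


def _effective_weights(p: np.ndarray, concentrations: np.ndarray | None) -> np.ndarray:
    """Mass-balance weights: q_jk = p_k c_jk / sum_k p_k c_jk (shape (..., K, J))."""
    if concentrations is None:
        raise ValueError("no concentrations given")
    num = p[..., :, None] * concentrations  # (..., K, J)
    return num / num.sum(axis=-2, keepdims=True)


def mixture_mean(
    p_row: np.ndarray,
    source_means: np.ndarray,
    discrimination_means: np.ndarray | None = None,
    concentrations: np.ndarray | None = None,
) -> np.ndarray:
    """Expected mixture tracer values for composition(s) ``p_row``.

    Without concentration dependence: sum_k p_k (mu_jk + lambda_jk).
    With it, the mass-balance ratio form:
    sum_k p_k c_jk (mu_jk + lambda_jk) / sum_k p_k c_jk.
    """
    p = np.asarray(p_row, dtype=float)
    base = np.asarray(source_means, dtype=float)
    if discrimination_means is not None:
        base = base + discrimination_means
    if concentrations is None:
        return p @ base
    q = _effective_weights(p, concentrations)
    return (q * base).sum(axis=-2)


def mixture_scale(
    p_row: np.ndarray,
    source_variances: np.ndarray,
    discrimination_sds: np.ndarray | None,
    state: ParameterState,
    error_spec: ErrorSpec,
    concentrations: np.ndarray | None = None,
    source_covs: np.ndarray | None = None,
) -> np.ndarray:
    """Mixture variance per tracer (or per-row JxJ covariance).

    * residual_only: sigma_j^2, independent of p.
    * process_only: sum_k p_k^2 (omega_jk^2 + tau_jk^2).
    * process_x_multiplicative: the process variance scaled by xi_j.

    With ``source_covs`` the weighted sum runs over source covariance
    matrices and a (..., J, J) covariance is returned (xi scales
    variances, preserving correlations).
    """
    p = np.asarray(p_row, dtype=float)
    j = np.asarray(source_variances).shape[-1]
    if error_spec.kind == "residual_only":
        if state.residual_sd is None:
            raise ValueError("residual_only requires residual_sd in the state")
        var = np.broadcast_to(state.residual_sd**2, p.shape[:-1] + (j,)).copy()
        return var

    if concentrations is None:
        w = p**2  # (..., K)
        w_jk = w[..., :, None]  # (..., K, J) broadcast
    else:
        q = _effective_weights(p, concentrations)  # (..., K, J)
        w_jk = q**2

    if source_covs is not None:
        tau2 = (
            np.zeros((source_covs.shape[0], j))
            if discrimination_sds is None
            else np.asarray(discrimination_sds) ** 2
        )
        covs = source_covs + np.apply_along_axis(np.diag, -1, tau2)  # (K, J, J)
        if concentrations is None:
            cov = np.einsum("...k,kab->...ab", p**2, covs)
        else:
            # off-diagonal weights use the geometric pairing of per-tracer weights
            qa = q[..., :, :, None]
            qb = q[..., :, None, :]
            cov = (qa * qb * covs).sum(axis=-3)
        if error_spec.kind == "process_x_multiplicative":
            if state.xi is None:
                raise ValueError("multiplicative error requires xi in the state")
            sx = np.sqrt(state.xi)
            cov = cov * (sx[:, None] * sx[None, :])
        return cov

    omega2 = np.asarray(source_variances, dtype=float)
    if discrimination_sds is not None:
        omega2 = omega2 + np.asarray(discrimination_sds) ** 2
    var = (w_jk * omega2).sum(axis=-2)  # (..., J)
    if error_spec.kind == "process_x_multiplicative":
        if state.xi is None:
            raise ValueError("multiplicative error requires xi in the state")
        var = var * state.xi
    return var


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

_LOG2PI = float(np.log(2.0 * np.pi))


def _normal_logpdf(y: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    return -0.5 * (_LOG2PI + np.log(var) + (y - mean) ** 2 / var)


def _mvn_logpdf_rows(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Row-wise MVN log density: y, mean (N, J); cov (N, J, J) or (J, J)."""
    d = y - mean
    if cov.ndim == 2:
        cov = np.broadcast_to(cov, (y.shape[0],) + cov.shape)
    chol = np.linalg.cholesky(cov)
    sol = np.linalg.solve(chol, d[..., None])[..., 0]
    logdet = 2.0 * np.log(np.einsum("nii->ni", chol)).sum(axis=-1)
    return -0.5 * (y.shape[-1] * _LOG2PI + logdet + (sol**2).sum(axis=-1))


def source_log_likelihood(
    state: ParameterState,
    model_spec: ModelSpec,
    sources: SourceData,
) -> float:
    """Log likelihood of the source data given the state's source parameters.

    raw: per-sample normal (or MVN with source_covs) terms.
    summary: sufficient-statistic densities -- the sample mean is normal
    with variance omega^2/n and (n-1)s^2/omega^2 is chi-square(n-1).
    fixed: no contribution (moments pinned to the inputs).
    """
    if model_spec.source_treatment == "fixed":
        return 0.0
    mu = state.source_means
    if mu is None:
        raise ValueError("non-fixed source treatment requires source parameters in state")
    if model_spec.source_treatment == "raw":
        total = 0.0
        for k, samp in enumerate(sources.raw_samples):
            if model_spec.use_covariance:
                total += _mvn_logpdf_rows(samp, mu[k], state.source_covs[k]).sum()
            else:
                total += _normal_logpdf(samp, mu[k], state.source_sds[k] ** 2).sum()
        return float(total)
    # summary treatment
    n = sources.sample_sizes[:, None].astype(float)  # (K, 1)
    omega2 = state.source_sds**2
    xbar, s = sources.means, sources.sds
    ll_mean = _normal_logpdf(xbar, mu, omega2 / n)
    # (n-1) s^2 / omega^2 ~ chi2(n-1)  <=>  (n-1)s^2 ~ Gamma((n-1)/2, scale 2 omega^2)
    a = (n - 1.0) / 2.0
    ss = (n - 1.0) * s**2
    ll_var = (a - 1.0) * np.log(ss) - ss / (2.0 * omega2) - a * np.log(2.0 * omega2) - gammaln(a)
    return float(ll_mean.sum() + ll_var.sum())


@dataclass
class PointwiseLogLik:
    """Per-consumer mixture log densities plus the scalar source-data term."""

    mixture: np.ndarray  # (N,)
    source: float

    @property
    def total(self) -> float:
        return float(self.mixture.sum() + self.source)


def log_likelihood_pointwise(
    state: ParameterState,
    model_spec: ModelSpec,
    mixture: MixtureData,
    sources: SourceData,
    discrimination: DiscriminationData,
    proportions: np.ndarray | None = None,
    design: DesignInfo | None = None,
) -> PointwiseLogLik:
    """Pointwise log likelihood: one joint term per consumer plus source terms.

    ``proportions`` (N, K) can be supplied to skip recomputing the
    linear predictor (the sampler does this).
    """
    if proportions is None:
        proportions = individual_proportions(state, model_spec.effects, mixture, design)
    mu = state.source_means if state.source_means is not None else sources.means
    if model_spec.use_covariance:
        source_var = None
        covs = state.source_covs
    else:
        sds = state.source_sds if state.source_sds is not None else sources.sds
        source_var = sds**2
        covs = None
    conc = sources.concentrations if model_spec.use_concentration else None

    mean = mixture_mean(proportions, mu, discrimination.means, conc)
    scale = mixture_scale(
        proportions,
        source_var if source_var is not None else np.zeros_like(mu),
        discrimination.sds,
        state,
        model_spec.error,
        concentrations=conc,
        source_covs=covs,
    )
    y = mixture.values
    if model_spec.use_covariance and model_spec.error.kind != "residual_only":
        row_ll = _mvn_logpdf_rows(y, mean, scale)
    else:
        if model_spec.use_covariance and model_spec.error.kind == "residual_only":
            scale = np.broadcast_to(state.residual_sd**2, y.shape)
        row_ll = _normal_logpdf(y, mean, scale).sum(axis=-1)
    if not np.all(np.isfinite(row_ll)):
        bad = int(np.nonzero(~np.isfinite(row_ll))[0][0])
        raise FloatingPointError(f"non-finite mixture log likelihood at row {bad}")
    return PointwiseLogLik(mixture=row_ll, source=source_log_likelihood(state, model_spec, sources))
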