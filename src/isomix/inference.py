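"""Posterior sampling, convergence diagnostics, summaries, and a
grid-posterior oracle for tiny models.

The sampler is an adaptive Metropolis-within-Gibbs over unconstrained
parameters (ILR coordinates, log variances, transformed bounded
parameters).  Proposal scales adapt per coordinate during burn-in to
target ~0.44 acceptance, then freeze.  Under a fixed seed the full draw
sequence is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logsumexp

from isomix.io import SourceData
from isomix.model import (
    DesignInfo,
    ErrorSpec,
    ModelSpec,
    ParameterState,
    TracerDataset,
    build_design,
    ilr_basis,
    ilr_dirichlet_logpdf,
    inverse_ilr,
)
from isomix.priors import DirichletPrior, default_prior

__all__ = [
    "McmcSettings",
    "PosteriorDraws",
    "fit",
    "convergence_diagnostics",
    "grid_posterior",
    "posterior_summary",
    "total_variation",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class McmcSettings:
    """Chain-length and adaptation settings.

    The defaults mirror a conservative desk-scale run; they are package
    defaults, not anyone's canonical values.  ``seed`` fixes the full
    draw sequence.
    """

    n_chains: int = 3
    n_iter: int = 100_000
    n_burn: int = 50_000
    thin: int = 50
    seed: int | None = None
    adapt_every: int = 25
    target_accept: float = 0.44

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.n_iter <= self.n_burn:
            raise ValueError("n_iter must exceed n_burn")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def preset(cls, name: str, seed: int | None = None, n_chains: int = 3) -> "McmcSettings":
        presets = {
            "test": dict(n_iter=3_000, n_burn=1_500, thin=1),
            "short": dict(n_iter=10_000, n_burn=5_000, thin=5),
            "normal": dict(n_iter=30_000, n_burn=15_000, thin=10),
            "long": dict(n_iter=100_000, n_burn=50_000, thin=50),
        }
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
        return cls(n_chains=n_chains, seed=seed, **presets[name])

    @property
    def n_saved(self) -> int:
        return (self.n_iter - self.n_burn + self.thin - 1) // self.thin


# ---------------------------------------------------------------------------
# posterior model: packing, priors, fast likelihood
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    name: str
    kind: str
    sl: slice
    shape: tuple[int, ...]


class _PosteriorModel:
    """Flattened unconstrained parameterization of the joint posterior."""

    def __init__(self, model_spec: ModelSpec, dataset: TracerDataset, prior_only: bool = False):
        model_spec.validate_for(dataset)
        self.spec = model_spec
        self.data = dataset
        self.prior_only = prior_only
        mix, src, disc = dataset.mixture, dataset.sources, dataset.discrimination
        self.n, self.j = mix.n, mix.n_tracers
        self.k = src.n_sources
        if model_spec.use_covariance and self.j > 2:
            raise NotImplementedError("covariance source treatment supports J <= 2")
        if model_spec.use_covariance and model_spec.use_concentration:
            raise NotImplementedError("covariance + concentration is not supported")
        self.prior = model_spec.prior or default_prior(self.k, src.source_names)
        if self.prior.n_sources != self.k:
            raise ValueError("prior length does not match number of sources")
        self.vp = model_spec.variance_priors
        self.design = build_design(model_spec.effects, mix)
        self.basis = ilr_basis(self.k)

        eff = model_spec.effects
        self.cat_codes = {f: mix.factor(f).codes for f in eff.fixed_categorical}
        self.cat_levels = {f: mix.factor(f).n_levels for f in eff.fixed_categorical}
        self.ran_codes = {f: mix.factor(f).codes for f in eff.random}
        self.ran_levels = {f: mix.factor(f).n_levels for f in eff.random}
        self.x_cont = {
            f: self.design.standardize(f, mix.covariate(f)) for f in eff.fixed_continuous
        }
        self.y = mix.values
        self.disc_mu = disc.means
        self.disc_var = disc.sds**2
        self.conc = src.concentrations if model_spec.use_concentration else None

        # residual sd upper bound: configured, else 10x data range per tracer
        rngs = self.y.max(axis=0) - self.y.min(axis=0)
        fallback = 10.0 * np.where(rngs > 0, rngs, 1.0)
        self.sigma_upper = (
            np.full(self.j, self.vp.residual_sd_upper)
            if self.vp.residual_sd_upper is not None
            else fallback
        )

        # raw-sample bookkeeping
        if src.treatment == "raw":
            self.raw_stack = np.vstack(src.raw_samples)
            self.raw_idx = np.repeat(np.arange(self.k), [s.shape[0] for s in src.raw_samples])
        else:
            self.raw_stack = self.raw_idx = None

        self.blocks: list[_Block] = []
        pos = 0

        def add(name: str, kind: str, shape: tuple[int, ...]) -> None:
            nonlocal pos
            size = int(np.prod(shape))
            self.blocks.append(_Block(name, kind, slice(pos, pos + size), shape))
            pos += size

        km1 = self.k - 1
        add("z0", "z0", (km1,))
        for f in eff.fixed_categorical:
            add(f"cat:{f}", "cat", (self.cat_levels[f] - 1, km1))
        for f in eff.fixed_continuous:
            add(f"cont:{f}", "cont", (km1,))
        for f in eff.random:
            add(f"ranef:{f}", "ranef", (self.ran_levels[f], km1))
            add(f"ranef_u:{f}", "ranef_u", (1,))
        if model_spec.error.kind == "residual_only":
            add("log_sigma", "log_sigma", (self.j,))
        elif model_spec.error.kind == "process_x_multiplicative":
            add("log_xi", "log_xi", (self.j,))
        if model_spec.source_treatment != "fixed":
            add("src_mu", "src_mu", (self.k, self.j))
            add("src_logw2", "src_logw2", (self.k, self.j))
            if model_spec.use_covariance and self.j == 2:
                add("src_rho_t", "src_rho_t", (self.k,))
        self.n_params = pos
        self._block_of = {b.name: b for b in self.blocks}

    # -- helpers -------------------------------------------------------------

    def get(self, theta: np.ndarray, name: str) -> np.ndarray:
        b = self._block_of[name]
        return theta[b.sl].reshape(b.shape)

    def has(self, name: str) -> bool:
        return name in self._block_of

    def initial(self, rng: np.random.Generator) -> np.ndarray:
        theta = np.zeros(self.n_params)
        src = self.data.sources
        for b in self.blocks:
            n = int(np.prod(b.shape))
            if b.kind == "z0":
                theta[b.sl] = 0.25 * rng.standard_normal(n)
            elif b.kind in ("cat", "cont"):
                theta[b.sl] = 0.25 * rng.standard_normal(n)
            elif b.kind == "ranef":
                theta[b.sl] = 0.05 * rng.standard_normal(n)
            elif b.kind == "ranef_u":
                theta[b.sl] = -1.0 + 0.5 * rng.standard_normal(n)
            elif b.kind == "log_sigma":
                sd = self.y.std(axis=0, ddof=1) if self.n > 1 else np.ones(self.j)
                sd = np.where(sd > 0, sd, 1.0)
                theta[b.sl] = np.log(sd) + 0.3 * rng.standard_normal(n)
            elif b.kind == "log_xi":
                theta[b.sl] = 0.3 * rng.standard_normal(n)
            elif b.kind == "src_mu":
                jit = 0.1 * (src.sds + 0.05) * rng.standard_normal(src.means.shape)
                theta[b.sl] = (src.means + jit).ravel()
            elif b.kind == "src_logw2":
                theta[b.sl] = np.log(src.sds.ravel() ** 2) + 0.2 * rng.standard_normal(n)
            elif b.kind == "src_rho_t":
                theta[b.sl] = 0.1 * rng.standard_normal(n)
        return theta

    # -- density -------------------------------------------------------------

    def log_posterior(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Returns (log posterior, per-consumer mixture log likelihood)."""
        spec, vp = self.spec, self.vp
        k, j, n = self.k, self.j, self.n
        lp = 0.0

        z0 = self.get(theta, "z0")
        lp += float(ilr_dirichlet_logpdf(z0, self.prior.alpha))

        # linear predictor -> proportions
        if spec.effects.is_intercept_only:
            z = z0[None, :]
        else:
            z = np.tile(z0, (n, 1))
            for f in spec.effects.fixed_categorical:
                coef = self.get(theta, f"cat:{f}")
                lp += -0.5 * float((coef**2).sum()) / vp.ilr_coefficient_sd**2
                full = np.vstack([np.zeros((1, coef.shape[1])), coef])
                z += full[self.cat_codes[f]]
            for f in spec.effects.fixed_continuous:
                beta = self.get(theta, f"cont:{f}")
                lp += -0.5 * float((beta**2).sum()) / vp.ilr_coefficient_sd**2
                z += self.x_cont[f][:, None] * beta[None, :]
            for f in spec.effects.random:
                off = self.get(theta, f"ranef:{f}")
                u = float(self.get(theta, f"ranef_u:{f}")[0])
                s = expit(u)
                gam2 = vp.random_effect_sd_upper**2 * s
                # uniform prior on gamma^2 in (0, upper^2); Jacobian of the logit map
                lp += math.log(s) + math.log1p(-s)
                lp += -0.5 * off.size * math.log(gam2) - 0.5 * float((off**2).sum()) / gam2
                z += off[self.ran_codes[f]]
        y_lin = z @ self.basis.T
        y_lin -= y_lin.max(axis=-1, keepdims=True)
        ey = np.exp(y_lin)
        p = ey / ey.sum(axis=-1, keepdims=True)  # (M, K), M in {1, N}

        # variance-structure parameters
        sigma2 = xi = None
        if spec.error.kind == "residual_only":
            w = self.get(theta, "log_sigma")
            sigma = np.exp(w)
            if np.any(sigma > self.sigma_upper):
                return -np.inf, np.full(n, -np.inf)
            lp += float(w.sum())  # Jacobian of log transform, U(0, upper) prior
            sigma2 = sigma**2
        elif spec.error.kind == "process_x_multiplicative":
            w = self.get(theta, "log_xi")
            xi = np.exp(w)
            lp += float(vp.xi_log_prior(xi).sum() + w.sum())

        # source parameters
        rho = None
        if spec.source_treatment != "fixed":
            mu = self.get(theta, "src_mu")
            lp += -0.5 * float((mu**2).sum()) / vp.source_mean_prior_sd**2
            w2 = self.get(theta, "src_logw2")
            # precision ~ Gamma(.001, .001): p(log w2) = -a*log w2 - b/w2
            lp += float((-0.001 * w2 - 0.001 * np.exp(-w2)).sum())
            omega2 = np.exp(w2)
            if self.has("src_rho_t"):
                t = self.get(theta, "src_rho_t")
                rho = np.tanh(t)
                lp += float(np.log1p(-(rho**2)).sum())  # uniform rho, Jacobian of tanh
            if not self.prior_only:
                lp += self._source_loglik(mu, omega2, rho)
        else:
            mu = self.data.sources.means
            omega2 = self.data.sources.sds**2

        if self.prior_only:
            return (lp, np.zeros(n)) if np.isfinite(lp) else (-np.inf, np.zeros(n))
        mix_ll = self._mixture_loglik(p, mu, omega2, sigma2, xi, rho)
        total = lp + float(mix_ll.sum())
        if not np.isfinite(total):
            return -np.inf, mix_ll
        return total, mix_ll

    def _source_loglik(self, mu: np.ndarray, omega2: np.ndarray, rho: np.ndarray | None) -> float:
        src = self.data.sources
        if src.treatment == "summary":
            nk = src.sample_sizes[:, None].astype(float)
            xbar, s = src.means, src.sds
            ll_mean = -0.5 * (
                _LOG2PI + np.log(omega2 / nk) + (xbar - mu) ** 2 * nk / omega2
            )
            a = (nk - 1.0) / 2.0
            ss = (nk - 1.0) * s**2
            ll_var = (a - 1.0) * np.log(ss) - ss / (2.0 * omega2) - a * np.log(2.0 * omega2) - gammaln(a)
            return float(ll_mean.sum() + ll_var.sum())
        # raw
        x = self.raw_stack
        idx = self.raw_idx
        if rho is None:
            m = mu[idx]
            v = omega2[idx]
            return float((-0.5 * (_LOG2PI + np.log(v) + (x - m) ** 2 / v)).sum())
        # bivariate normal per source
        d = x - mu[idx]
        v1, v2 = omega2[idx, 0], omega2[idx, 1]
        r = rho[idx]
        om = 1.0 - r**2
        quad = d[:, 0] ** 2 / v1 - 2.0 * r * d[:, 0] * d[:, 1] / np.sqrt(v1 * v2) + d[:, 1] ** 2 / v2
        ll = -_LOG2PI - 0.5 * np.log(v1 * v2 * om) - quad / (2.0 * om)
        return float(ll.sum())

    def _mixture_loglik(
        self,
        p: np.ndarray,
        mu: np.ndarray,
        omega2: np.ndarray,
        sigma2: np.ndarray | None,
        xi: np.ndarray | None,
        rho: np.ndarray | None,
    ) -> np.ndarray:
        spec = self.spec
        base = mu + self.disc_mu  # (K, J)
        if self.conc is None:
            mean = p @ base  # (M, J)
        else:
            num = p[:, :, None] * self.conc  # (M, K, J)
            q = num / num.sum(axis=1, keepdims=True)
            mean = (q * base).sum(axis=1)

        if spec.error.kind == "residual_only":
            var = sigma2[None, :]
            ll = -0.5 * (_LOG2PI + np.log(var) + (self.y - mean) ** 2 / var)
            return ll.sum(axis=-1)

        pvar = omega2 + self.disc_var  # (K, J)
        if self.conc is None:
            w = p**2  # (M, K)
        else:
            w = None  # handled via q below
        if rho is not None:
            # bivariate mixture covariance (J = 2)
            p2 = p**2
            c11 = p2 @ pvar[:, 0]
            c22 = p2 @ pvar[:, 1]
            c12 = p2 @ (rho * np.sqrt(omega2[:, 0] * omega2[:, 1]))
            if xi is not None:
                c11 = c11 * xi[0]
                c22 = c22 * xi[1]
                c12 = c12 * math.sqrt(xi[0] * xi[1])
            d1 = self.y[:, 0] - mean[..., 0]
            d2 = self.y[:, 1] - mean[..., 1]
            om = c11 * c22 - c12**2
            quad = (c22 * d1**2 - 2.0 * c12 * d1 * d2 + c11 * d2**2) / om
            return -_LOG2PI - 0.5 * (np.log(om) + quad)
        if w is not None:
            var = w @ pvar  # (M, J)
        else:
            var = ((q**2) * pvar).sum(axis=1)
        if xi is not None:
            var = var * xi[None, :]
        ll = -0.5 * (_LOG2PI + np.log(var) + (self.y - mean) ** 2 / var)
        return ll.sum(axis=-1)

    # -- state reconstruction ------------------------------------------------

    def state_from(self, theta: np.ndarray) -> ParameterState:
        spec = self.spec
        state = ParameterState(ilr_intercept=self.get(theta, "z0").copy())
        for f in spec.effects.fixed_categorical:
            state.fixed_categorical[f] = self.get(theta, f"cat:{f}").copy()
        for f in spec.effects.fixed_continuous:
            state.fixed_continuous[f] = self.get(theta, f"cont:{f}").copy()
        for f in spec.effects.random:
            state.random_offsets[f] = self.get(theta, f"ranef:{f}").copy()
            u = float(self.get(theta, f"ranef_u:{f}")[0])
            state.random_sds[f] = float(
                self.vp.random_effect_sd_upper * math.sqrt(expit(u))
            )
        if spec.error.kind == "residual_only":
            state.residual_sd = np.exp(self.get(theta, "log_sigma"))
        elif spec.error.kind == "process_x_multiplicative":
            state.xi = np.exp(self.get(theta, "log_xi"))
        if spec.source_treatment != "fixed":
            state.source_means = self.get(theta, "src_mu").copy()
            state.source_sds = np.sqrt(np.exp(self.get(theta, "src_logw2")))
            if self.has("src_rho_t"):
                rho = np.tanh(self.get(theta, "src_rho_t"))
                sds = state.source_sds
                covs = np.empty((self.k, 2, 2))
                covs[:, 0, 0] = sds[:, 0] ** 2
                covs[:, 1, 1] = sds[:, 1] ** 2
                covs[:, 0, 1] = covs[:, 1, 0] = rho * sds[:, 0] * sds[:, 1]
                state.source_covs = covs
        else:
            state.source_means = self.data.sources.means.copy()
            state.source_sds = self.data.sources.sds.copy()
        return state


# ---------------------------------------------------------------------------
# posterior draws container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """MCMC output: per-block draws, derived proportions, pointwise log lik."""

    params: dict[str, np.ndarray]  # name -> (C, S, ...)
    p_global: np.ndarray  # (C, S, K)
    loglik: np.ndarray  # (C, S, N) pointwise mixture log likelihood
    source_names: list[str]
    tracer_names: list[str]
    meta: dict = field(default_factory=dict)
    design: DesignInfo | None = None

    def __post_init__(self) -> None:
        c, s, k = self.p_global.shape
        if not np.allclose(self.p_global.sum(axis=-1), 1.0, atol=1e-8):
            raise ValueError("saved proportion draws must lie on the simplex")
        if self.loglik.shape[:2] != (c, s):
            raise ValueError("loglik shape inconsistent with draws")

    @property
    def n_chains(self) -> int:
        return self.p_global.shape[0]

    @property
    def n_saved(self) -> int:
        return self.p_global.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of a block pooled over chains: (C*S, ...)."""
        if name == "p_global":
            arr = self.p_global
        else:
            arr = self.params[name]
        return arr.reshape((-1,) + arr.shape[2:])

    def scalar_draws(self) -> dict[str, np.ndarray]:
        """Flatten every block to named scalar series of shape (C, S)."""
        out: dict[str, np.ndarray] = {}
        for name, arr in self.params.items():
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            labels = _scalar_labels(name, arr.shape[2:], self.source_names, self.tracer_names)
            for i, lab in enumerate(labels):
                out[lab] = flat[:, :, i]
        for k, src in enumerate(self.source_names):
            out[f"p_global[{src}]"] = self.p_global[:, :, k]
        return out

    # -- persistence ---------------------------------------------------------

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        scalars = self.scalar_draws()
        c, s = self.n_chains, self.n_saved
        df = pd.DataFrame({k: v.reshape(-1) for k, v in scalars.items()})
        df.insert(0, "chain", np.repeat(np.arange(c), s))
        df.insert(1, "draw", np.tile(np.arange(s), c))
        df.to_csv(path / "draws.csv", index=False, float_format="%.17g")
        ll = pd.DataFrame(self.loglik.reshape(c * s, -1))
        ll.to_csv(path / "loglik.csv", index=False, float_format="%.17g")
        manifest = {
            "meta": _jsonable(self.meta),
            "source_names": self.source_names,
            "tracer_names": self.tracer_names,
            "shapes": {k: list(v.shape) for k, v in self.params.items()},
            "n_chains": c,
            "n_saved": s,
            "design": None if self.design is None else _design_to_dict(self.design),
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def from_dir(cls, path: str | Path) -> "PosteriorDraws":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        c, s = manifest["n_chains"], manifest["n_saved"]
        src_names = manifest["source_names"]
        trc_names = manifest["tracer_names"]
        df = pd.read_csv(path / "draws.csv")
        params: dict[str, np.ndarray] = {}
        for name, shape in manifest["shapes"].items():
            labels = _scalar_labels(name, tuple(shape[2:]), src_names, trc_names)
            arr = np.stack([df[lab].to_numpy() for lab in labels], axis=-1)
            params[name] = arr.reshape([c, s] + list(shape[2:]))
        p_cols = [f"p_global[{sn}]" for sn in src_names]
        p_global = np.stack([df[cn].to_numpy() for cn in p_cols], axis=-1).reshape(c, s, -1)
        ll = pd.read_csv(path / "loglik.csv").to_numpy().reshape(c, s, -1)
        design = manifest.get("design")
        return cls(
            params=params,
            p_global=p_global,
            loglik=ll,
            source_names=src_names,
            tracer_names=trc_names,
            meta=manifest.get("meta", {}),
            design=None if design is None else _design_from_dict(design),
        )


def _scalar_labels(name, shape, source_names, tracer_names) -> list[str]:
    if not shape:
        return [name]
    idx_sets = []
    for dim, size in enumerate(shape):
        if name in ("src_mu", "src_logw2", "src_omega"):
            labels = source_names if dim == 0 else tracer_names
        elif name in ("xi", "sigma", "log_xi", "log_sigma") and size == len(tracer_names):
            labels = tracer_names
        elif name == "src_rho":
            labels = source_names
        else:
            labels = [str(i) for i in range(size)]
        idx_sets.append([str(x) for x in labels[:size]])
    out = []
    import itertools

    for combo in itertools.product(*idx_sets):
        out.append(f"{name}[{','.join(combo)}]")
    return out


def _design_to_dict(design: DesignInfo) -> dict:
    return {
        "fixed_categorical": list(design.effects.fixed_categorical),
        "fixed_continuous": list(design.effects.fixed_continuous),
        "random": list(design.effects.random),
        "factor_levels": design.factor_levels,
        "covariate_center": design.covariate_center,
        "covariate_scale": design.covariate_scale,
        "covariate_range": {k: list(v) for k, v in design.covariate_range.items()},
    }


def _design_from_dict(d: dict) -> DesignInfo:
    from isomix.model import EffectDesign

    return DesignInfo(
        effects=EffectDesign(
            fixed_categorical=tuple(d["fixed_categorical"]),
            fixed_continuous=tuple(d["fixed_continuous"]),
            random=tuple(d["random"]),
        ),
        factor_levels={k: list(v) for k, v in d["factor_levels"].items()},
        covariate_center={k: float(v) for k, v in d["covariate_center"].items()},
        covariate_scale={k: float(v) for k, v in d["covariate_scale"].items()},
        covariate_range={k: (float(v[0]), float(v[1])) for k, v in d["covariate_range"].items()},
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


def _run_chain(
    pm: _PosteriorModel,
    settings: McmcSettings,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    theta = pm.initial(rng)
    lp, mix_ll = pm.log_posterior(theta)
    tries = 0
    while not np.isfinite(lp):
        theta = pm.initial(rng)
        lp, mix_ll = pm.log_posterior(theta)
        tries += 1
        if tries > 50:
            raise RuntimeError(f"could not find a finite starting point; last state {theta}")

    npar = pm.n_params
    scales = np.full(npar, 0.3)
    acc = np.zeros(npar)
    n_save = settings.n_saved
    saved_theta = np.empty((n_save, npar))
    saved_ll = np.empty((n_save, pm.n))
    s_idx = 0
    adapt_count = 0

    for it in range(settings.n_iter):
        for c in range(npar):
            old = theta[c]
            theta[c] = old + scales[c] * rng.standard_normal()
            lp_new, mix_new = pm.log_posterior(theta)
            if np.log(rng.random()) < lp_new - lp:
                lp, mix_ll = lp_new, mix_new
                acc[c] += 1
            else:
                theta[c] = old
        if it < settings.n_burn and (it + 1) % settings.adapt_every == 0:
            adapt_count += 1
            rate = acc / settings.adapt_every
            delta = min(0.25, 1.0 / math.sqrt(adapt_count))
            scales *= np.exp(delta * np.where(rate > settings.target_accept, 1.0, -1.0))
            scales = np.clip(scales, 1e-4, 50.0)
            acc[:] = 0.0
        if it >= settings.n_burn and (it - settings.n_burn) % settings.thin == 0:
            saved_theta[s_idx] = theta
            saved_ll[s_idx] = mix_ll
            s_idx += 1
    if not np.isfinite(lp):
        raise RuntimeError("sampler left the support; final state saved in exception")
    return saved_theta[:s_idx], saved_ll[:s_idx]


def fit(
    model_spec: ModelSpec,
    dataset: TracerDataset,
    settings: McmcSettings | None = None,
    prior_only: bool = False,
) -> PosteriorDraws:
    """Sample the posterior; reproducible under a fixed seed.

    With a single mixture row the error structure is switched to
    ``process_only`` automatically (a residual/multiplicative variance is
    not estimable from one observation).  ``prior_only`` disables the
    likelihood so the joint prior can be inspected in proportion space.
    """
    settings = settings or McmcSettings()
    if dataset.mixture.n == 1 and model_spec.error.kind != "process_only":
        warnings.warn("single mixture row: selecting process_only error structure")
        model_spec = replace(model_spec, error=ErrorSpec("process_only"))
    pm = _PosteriorModel(model_spec, dataset, prior_only=prior_only)

    seed_seq = np.random.SeedSequence(settings.seed)
    child_seqs = seed_seq.spawn(settings.n_chains)
    thetas, lls = [], []
    for cs in child_seqs:
        rng = np.random.Generator(np.random.PCG64(cs))
        t, ll = _run_chain(pm, settings, rng)
        thetas.append(t)
        lls.append(ll)
    theta_arr = np.stack(thetas)  # (C, S, P)
    ll_arr = np.stack(lls)

    c, s, _ = theta_arr.shape
    params: dict[str, np.ndarray] = {}
    for b in pm.blocks:
        raw = theta_arr[:, :, b.sl].reshape((c, s) + b.shape)
        if b.kind == "log_sigma":
            params["sigma"] = np.exp(raw)
        elif b.kind == "log_xi":
            params["xi"] = np.exp(raw)
        elif b.kind == "src_logw2":
            params["src_omega"] = np.sqrt(np.exp(raw))
        elif b.kind == "ranef_u":
            f = b.name.split(":", 1)[1]
            gam2 = pm.vp.random_effect_sd_upper**2 * expit(raw[..., 0])
            params[f"ranef_var:{f}"] = gam2
        elif b.kind == "src_rho_t":
            params["src_rho"] = np.tanh(raw)
        else:
            params[b.name] = raw
    p_global = inverse_ilr(theta_arr[:, :, pm._block_of["z0"].sl], basis=pm.basis)

    meta = {
        "seed": settings.seed,
        "settings": {
            "n_chains": settings.n_chains,
            "n_iter": settings.n_iter,
            "n_burn": settings.n_burn,
            "thin": settings.thin,
        },
        "model": model_spec.to_dict(),
        "data_hash": dataset.data_hash(),
        "n_obs": pm.n,
        "prior_alpha": pm.prior.alpha.tolist(),
    }
    return PosteriorDraws(
        params=params,
        p_global=p_global,
        loglik=ll_arr,
        source_names=list(dataset.sources.source_names),
        tracer_names=list(dataset.sources.tracer_names),
        meta=meta,
        design=pm.design,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def _split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of a (C, S) draw array."""
    c, s = x.shape
    half = s // 2
    if half < 2:
        return float("nan")
    seqs = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = seqs.shape
    means = seqs.mean(axis=1)
    variances = seqs.var(axis=1, ddof=1)
    w = variances.mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return float("nan")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke z-score for one pooled chain (batch-mean variance estimate)."""
    n = x.size
    a = x[: max(2, int(first * n))]
    b = x[-max(2, int(last * n)) :]

    def se(seg: np.ndarray) -> float:
        nb = max(2, int(np.sqrt(seg.size)))
        batches = np.array_split(seg, nb)
        bm = np.array([bb.mean() for bb in batches])
        return float(bm.std(ddof=1) / np.sqrt(nb))

    denom = math.hypot(se(a), se(b))
    if denom == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / denom)


def convergence_diagnostics(draws: PosteriorDraws, rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Split-R-hat and Geweke z per scalar parameter, with pass/fail flags.

    With a single chain R-hat is unavailable (NaN) and a warning is
    emitted; zero-variance parameters are reported as degenerate rather
    than dividing by zero.
    """
    scalars = draws.scalar_draws()
    if draws.n_chains < 2:
        warnings.warn("R-hat requires >= 2 chains; reporting Geweke z only")
    rows = []
    for name, x in scalars.items():
        degenerate = bool(np.allclose(x, x.reshape(-1)[0]))
        rhat = float("nan") if (draws.n_chains < 2 or degenerate) else _split_rhat(x)
        gz = float("nan") if degenerate else _geweke_z(x.reshape(-1))
        # the pass/fail gate is R-hat; Geweke is advisory (its batch-mean
        # SE is noisy at short run lengths)
        ok = degenerate or math.isnan(rhat) or rhat <= rhat_threshold
        rows.append(
            {
                "parameter": name,
                "rhat": rhat,
                "geweke_z": gz,
                "geweke_flag": bool(np.isfinite(gz) and abs(gz) > 3),
                "degenerate": degenerate,
                "pass": ok,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["all_pass"] = bool(df["pass"].all())
    return df


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def posterior_summary(
    draws: PosteriorDraws,
    quantiles: tuple[float, ...] = (0.025, 0.05, 0.25, 0.5, 0.75, 0.95, 0.975),
) -> pd.DataFrame:
    """Mean, median, and equal-tailed intervals for every scalar quantity.

    Includes the derived global proportions and the specialization index
    of the global composition.
    """
    from isomix.posthoc import specialization_index

    scalars = draws.scalar_draws()
    scalars["epsilon(p_global)"] = specialization_index(draws.p_global).reshape(
        draws.n_chains, draws.n_saved
    )
    rows = []
    for name, x in scalars.items():
        flat = x.reshape(-1)
        row = {"parameter": name, "mean": flat.mean(), "sd": flat.std(ddof=1), "median": np.median(flat)}
        for q in quantiles:
            row[f"q{q:g}"] = np.quantile(flat, q)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# grid-posterior oracle (K = 2, fixed sources, no covariates)
# ---------------------------------------------------------------------------


def grid_posterior(
    model_spec: ModelSpec,
    dataset: TracerDataset,
    grid_resolution: int = 400,
    nuisance_grid: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force discrete posterior over p_1 for tiny two-source models.

    Supports K=2, J<=2, fixed sources, intercept-only.  Per-tracer
    nuisance parameters (sigma or xi) are marginalized on a dense grid
    weighted by their priors.  Returns (grid midpoints, normalized pmf).
    """
    if dataset.n_sources != 2:
        raise ValueError("grid_posterior supports exactly 2 sources")
    if dataset.n_tracers > 2:
        raise ValueError("grid_posterior supports at most 2 tracers")
    if not model_spec.effects.is_intercept_only:
        raise ValueError("grid_posterior supports intercept-only models")
    if model_spec.source_treatment != "fixed" or dataset.sources.treatment != "fixed":
        raise ValueError("grid_posterior requires fixed sources")
    if grid_resolution < 200:
        raise ValueError("grid_resolution must be >= 200")
    model_spec.validate_for(dataset)

    pm = _PosteriorModel(model_spec, dataset)
    alpha = pm.prior.alpha
    r = grid_resolution
    p1 = (np.arange(r) + 0.5) / r
    p = np.column_stack([p1, 1.0 - p1])  # (R, 2)

    base = dataset.sources.means + dataset.discrimination.means  # (2, J)
    if model_spec.use_concentration:
        conc = dataset.sources.concentrations
        num = p[:, :, None] * conc
        q = num / num.sum(axis=1, keepdims=True)
        mean = (q * base).sum(axis=1)
        w2 = q**2
    else:
        mean = p @ base
        w2 = (p**2)[:, :, None]
    pvar = dataset.sources.sds**2 + dataset.discrimination.sds**2  # (2, J)
    process_var = (w2 * pvar).sum(axis=1)  # (R, J)

    y = dataset.mixture.values  # (N, J)
    log_prior = (alpha[0] - 1.0) * np.log(p1) + (alpha[1] - 1.0) * np.log(1.0 - p1)

    log_post = log_prior.copy()
    for j in range(dataset.n_tracers):
        yj = y[:, j]
        mj = mean[:, j]  # (R,)
        if model_spec.error.kind == "process_only":
            var = process_var[:, j][:, None]  # (R, 1)
            ll = -0.5 * (_LOG2PI + np.log(var) + (yj[None, :] - mj[:, None]) ** 2 / var)
            log_post += ll.sum(axis=1)
            continue
        if model_spec.error.kind == "residual_only":
            upper = pm.sigma_upper[j]
            g = nuisance_grid
            sig = (np.arange(g) + 0.5) / g * upper
            var_g = sig**2  # (G,)
            log_w = np.full(g, -np.log(g))  # uniform prior weights
            var = var_g[None, :]  # same for all p
            sse = ((yj[None, :] - mj[:, None]) ** 2).sum(axis=1)  # (R,)
            n_obs = yj.size
            ll = (
                -0.5 * n_obs * (_LOG2PI + np.log(var))
                - 0.5 * sse[:, None] / var
            )  # (R, G)
        else:  # process_x_multiplicative
            g = nuisance_grid
            u = np.linspace(-9.0, 9.0, g)
            xi = np.exp(u)
            du = u[1] - u[0]
            log_w = pm.vp.xi_log_prior(xi) + np.log(xi) + np.log(du)
            var = process_var[:, j][:, None] * xi[None, :]  # (R, G)
            sse = ((yj[None, :] - mj[:, None]) ** 2).sum(axis=1)
            n_obs = yj.size
            ll = -0.5 * n_obs * (_LOG2PI + np.log(var)) - 0.5 * sse[:, None] / var
        log_post += logsumexp(ll + log_w[None, :], axis=1)

    log_post -= log_post.max()
    pmf = np.exp(log_post)
    pmf /= pmf.sum()
    return p1, pmf


def total_variation(
    draws_p1: np.ndarray,
    grid: np.ndarray,
    pmf: np.ndarray,
    n_bins: int = 40,
) -> float:
    """TV distance between MCMC draws of p_1 and a grid pmf, on common bins."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mc_counts, _ = np.histogram(draws_p1, bins=edges)
    mc = mc_counts / mc_counts.sum()
    idx = np.clip(np.digitize(grid, edges) - 1, 0, n_bins - 1)
    gr = np.bincount(idx, weights=pmf, minlength=n_bins)
    return 0.5 * float(np.abs(mc - gr).sum())
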