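"""Dirichlet priors on source proportions and defaults for everything else.

The default prior is the "uninformative"/generalist Dirichlet with all
hyperparameters equal to 1: uniform over the simplex, but not uniform
in each marginal.  Informative priors built from auxiliary counts
(e.g., stomach contents) can be rescaled to a chosen total weight so
that the prior mean is kept while its informativeness is reduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DirichletPrior",
    "VariancePriorSpec",
    "default_prior",
    "informative_prior_from_counts",
    "aggregate_prior",
    "prior_marginal_summary",
]


@dataclass
class DirichletPrior:
    """Dirichlet hyperparameters over the K source proportions."""

    alpha: np.ndarray
    source_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.ndim != 1 or self.alpha.size < 2:
            raise ValueError("alpha must be a vector of length >= 2")
        if np.any(self.alpha <= 0) or not np.all(np.isfinite(self.alpha)):
            raise ValueError("all Dirichlet hyperparameters must be positive and finite")
        if self.source_names is None:
            self.source_names = [f"source_{k + 1}" for k in range(self.alpha.size)]
        elif len(self.source_names) != self.alpha.size:
            raise ValueError("source_names length must match alpha")

    @property
    def n_sources(self) -> int:
        return self.alpha.size

    @property
    def mean(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()

    def sample(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        return rng.dirichlet(self.alpha, size=n_draws)


@dataclass
class VariancePriorSpec:
    """Weakly informative priors for all non-compositional parameters.

    * residual SD: Uniform(0, ``residual_sd_upper``); ``None`` defers to a
      data-driven bound (10x the mixture data range per tracer).
    * multiplicative error xi: a named positive-line family,
      ``("halfcauchy", scale)`` (default, heavy-tailed so both xi << 1
      and xi >> 1 are admissible) or ``("chisq", df)``.
    * ILR-space coefficients: zero-mean normal, SD sqrt(1000) -- the
      diffuse N(0, 1000) used for fixed-effect slopes.
    * random-effect SD: Uniform(0, sqrt(20)), i.e. U(0, 20) on the
      variance scale.
    """

    residual_sd_upper: float | None = None
    multiplicative_xi_prior: tuple[str, float] = ("halfcauchy", 1.0)
    random_effect_sd_upper: float = float(np.sqrt(20.0))
    ilr_coefficient_sd: float = float(np.sqrt(1000.0))
    source_mean_prior_sd: float = 1000.0

    def __post_init__(self) -> None:
        for name, val in [
            ("random_effect_sd_upper", self.random_effect_sd_upper),
            ("ilr_coefficient_sd", self.ilr_coefficient_sd),
            ("source_mean_prior_sd", self.source_mean_prior_sd),
        ]:
            if not (np.isfinite(val) and val > 0):
                raise ValueError(f"{name} must be positive and finite")
        if self.residual_sd_upper is not None and not (
            np.isfinite(self.residual_sd_upper) and self.residual_sd_upper > 0
        ):
            raise ValueError("residual_sd_upper must be positive and finite")
        family, param = self.multiplicative_xi_prior
        if family not in ("halfcauchy", "chisq"):
            raise ValueError(f"unknown xi prior family {family!r}")
        if not (np.isfinite(param) and param > 0):
            raise ValueError("xi prior parameter must be positive and finite")

    def xi_log_prior(self, xi: np.ndarray) -> np.ndarray:
        """Unnormalized log prior density of xi (elementwise)."""
        xi = np.asarray(xi, dtype=float)
        family, param = self.multiplicative_xi_prior
        if family == "halfcauchy":
            return -np.log1p((xi / param) ** 2)
        # chi-square with df = param
        return (param / 2.0 - 1.0) * np.log(xi) - xi / 2.0


def default_prior(n_sources: int, source_names: Sequence[str] | None = None) -> DirichletPrior:
    """The "uninformative"/generalist prior: all alpha_k = 1."""
    if n_sources < 2:
        raise ValueError("a mixing model needs at least 2 sources")
    return DirichletPrior(
        alpha=np.ones(n_sources),
        source_names=list(source_names) if source_names is not None else None,
    )


def informative_prior_from_counts(
    counts: Sequence[float],
    total_weight: float | str | None = "auto",
    source_names: Sequence[str] | None = None,
) -> DirichletPrior:
    """Build a Dirichlet prior from auxiliary counts (e.g., stomach contents).

    With ``total_weight=None`` the counts are used as hyperparameters
    directly (a very informative prior whose weight is the total count).
    Otherwise the counts are rescaled to sum to ``total_weight``
    (``"auto"`` = the number of sources K, the same weight as the
    generalist prior):

        alpha_k = total_weight * n_k / sum(n_k)

    The prior mean counts/sum(counts) is preserved in both cases.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("counts must be a vector of length >= 2")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.count_nonzero(counts) < 2:
        raise ValueError("need at least two strictly positive counts")
    if total_weight == "auto":
        total_weight = float(counts.size)
    if total_weight is None:
        alpha = counts.copy()
        if np.any(alpha == 0):
            raise ValueError(
                "zero count gives alpha_k = 0, which is not a valid Dirichlet "
                "hyperparameter; add a pseudo-count to that source explicitly"
            )
    else:
        if not (np.isfinite(total_weight) and total_weight > 0):
            raise ValueError("total_weight must be positive and finite")
        if np.any(counts == 0):
            raise ValueError(
                "rescaling a zero count gives alpha_k = 0, which violates "
                "Dirichlet positivity; add a pseudo-count to that source explicitly"
            )
        alpha = total_weight * counts / counts.sum()
    return DirichletPrior(alpha=alpha, source_names=list(source_names) if source_names else None)


def aggregate_prior(
    prior: DirichletPrior,
    grouping: Mapping[str, str],
    group_order: Sequence[str] | None = None,
) -> DirichletPrior:
    """Dirichlet prior implied for aggregated sources: group alpha = sum of members.

    Aggregating posteriors silently aggregates the prior too -- combining
    two generalist-prior sources yields a combined prior with twice the
    weight of the others.  This function makes that implied prior
    explicit so it can be shown to the user as a warning.
    """
    names = prior.source_names
    missing = [s for s in names if s not in grouping]
    if missing:
        raise ValueError(f"grouping does not assign source(s) {missing}")
    unknown = [s for s in grouping if s not in names]
    if unknown:
        raise ValueError(f"grouping references unknown source(s) {unknown}")
    if group_order is None:
        group_order = list(dict.fromkeys(grouping[s] for s in names))
    alpha = np.zeros(len(group_order))
    for k, s in enumerate(names):
        g = grouping[s]
        if g not in group_order:
            raise ValueError(f"group {g!r} not in group_order")
        alpha[group_order.index(g)] += prior.alpha[k]
    if np.any(alpha == 0):
        empty = [g for g, a in zip(group_order, alpha) if a == 0]
        raise ValueError(f"empty group(s) {empty}")
    return DirichletPrior(alpha=alpha, source_names=list(group_order))


def prior_marginal_summary(
    prior: DirichletPrior,
    n_draws: int = 10_000,
    seed: int | None = None,
    quantiles: Sequence[float] = (0.025, 0.25, 0.5, 0.75, 0.975),
) -> pd.DataFrame:
    """Monte-Carlo summary of the per-source marginal prior distributions.

    Deterministic under a fixed seed; marginal means converge to
    alpha_k / sum(alpha).
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000 for stable summaries")
    rng = np.random.default_rng(seed)
    draws = prior.sample(n_draws, rng)
    rows = {
        "source": prior.source_names,
        "analytic_mean": prior.mean,
        "mc_mean": draws.mean(axis=0),
        "mc_sd": draws.std(axis=0, ddof=1),
    }
    qs = np.quantile(draws, quantiles, axis=0)
    for q, row in zip(quantiles, qs):
        rows[f"q{q:g}"] = row
    return pd.DataFrame(rows)
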