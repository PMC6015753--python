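"""Post-processing of posterior draws: source combining, specialization
indices, covariate predictions, and the mixing-polygon diagnostic."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from isomix.io import DiscriminationData, MixtureData, SourceData
from isomix.model import ilr_basis
from isomix.priors import DirichletPrior, aggregate_prior
from isomix.inference import PosteriorDraws

__all__ = [
    "SourceGrouping",
    "combine_sources",
    "specialization_index",
    "predict_proportions",
    "calc_area",
]


@dataclass(frozen=True)
class SourceGrouping:
    """Surjective map from original source names onto group names."""

    mapping: Mapping[str, str]
    group_order: tuple[str, ...] | None = None

    def resolved_order(self, source_names: Sequence[str]) -> list[str]:
        if self.group_order is not None:
            return list(self.group_order)
        return list(dict.fromkeys(self.mapping[s] for s in source_names))

    def validate_for(self, source_names: Sequence[str]) -> None:
        missing = [s for s in source_names if s not in self.mapping]
        if missing:
            raise ValueError(f"grouping does not assign source(s) {missing}")
        unknown = [s for s in self.mapping if s not in source_names]
        if unknown:
            raise ValueError(f"grouping references unknown source(s) {unknown}")
        order = self.resolved_order(source_names)
        used = set(self.mapping[s] for s in source_names)
        empty = [g for g in order if g not in used]
        if empty:
            raise ValueError(f"empty group(s) {empty}")


def combine_sources(
    draws: PosteriorDraws,
    grouping: SourceGrouping | Mapping[str, str],
) -> tuple[PosteriorDraws, DirichletPrior]:
    """Aggregate posterior proportion draws a posteriori.

    For each draw the combined proportion is the sum of the member
    proportions, preserving between-source correlation.  The second
    return value is the *implied aggregated prior* (member alphas
    summed): aggregating posteriors aggregates prior weight too, so it
    should be shown to the user as a warning.
    """
    if not isinstance(grouping, SourceGrouping):
        grouping = SourceGrouping(mapping=dict(grouping))
    names = draws.source_names
    grouping.validate_for(names)
    order = grouping.resolved_order(names)
    g_idx = np.array([order.index(grouping.mapping[s]) for s in names])
    n_groups = len(order)

    def regroup(p: np.ndarray) -> np.ndarray:
        out = np.zeros(p.shape[:-1] + (n_groups,))
        for k, g in enumerate(g_idx):
            out[..., g] += p[..., k]
        return out

    alpha = np.asarray(draws.meta.get("prior_alpha", np.ones(len(names))), dtype=float)
    original_prior = DirichletPrior(alpha=alpha, source_names=list(names))
    implied_prior = aggregate_prior(original_prior, dict(grouping.mapping), order)

    combined = replace(
        draws,
        p_global=regroup(draws.p_global),
        source_names=order,
        params={k: v for k, v in draws.params.items() if not k.startswith(("z0", "cat:", "cont:", "ranef:"))},
        meta={**draws.meta, "combined_from": list(names), "implied_prior_alpha": implied_prior.alpha.tolist()},
    )
    return combined, implied_prior


def specialization_index(p: np.ndarray) -> np.ndarray | float:
    """Normalized distance from the generalist barycenter.

    epsilon = sqrt( (K/(K-1)) * sum_k (p_k - 1/K)^2 ): 0 for the perfect
    generalist (all p_k = 1/K), 1 at any vertex of the simplex.
    Applies along the last axis, so it can be evaluated draw-wise.
    """
    p = np.asarray(p, dtype=float)
    k = p.shape[-1]
    eps = np.sqrt(k / (k - 1.0) * ((p - 1.0 / k) ** 2).sum(axis=-1))
    return float(eps) if eps.ndim == 0 else eps


def predict_proportions(
    draws: PosteriorDraws,
    covariates: Mapping[str, Sequence] | pd.DataFrame,
    quantiles: tuple[float, ...] = (0.05, 0.5, 0.95),
    allow_extrapolation: bool = False,
    include_random: bool = False,
) -> dict:
    """Posterior of p at new covariate values via the fitted linear predictor.

    ``covariates`` maps each effect name to a vector of raw-scale values
    (continuous) or level labels (categorical); all vectors share length
    G.  Random-effect offsets are excluded by default (population-level
    prediction).  Returns draws (G, n_draws, K) plus summary quantiles.
    """
    design = draws.design
    if design is None:
        raise ValueError("draws carry no design information; was the model fit with covariates?")
    eff = design.effects
    cov = dict(covariates) if not isinstance(covariates, pd.DataFrame) else {
        c: covariates[c].tolist() for c in covariates.columns
    }
    needed = list(eff.fixed_categorical) + list(eff.fixed_continuous)
    lengths = {len(np.atleast_1d(cov[name])) for name in needed} if needed else {1}
    if len(lengths) > 1:
        raise ValueError("all covariate vectors must share one length")
    g = lengths.pop()

    n_draws = draws.n_chains * draws.n_saved
    km1 = len(draws.source_names) - 1
    z = np.broadcast_to(
        draws.stacked("z0"), (g, n_draws, km1)
    ).copy()  # (G, S, K-1)
    for name in eff.fixed_categorical:
        labels = [str(v) for v in np.atleast_1d(cov[name])]
        codes = design.level_codes(name, labels)
        coef = draws.stacked(f"cat:{name}")  # (S, L-1, K-1)
        full = np.concatenate([np.zeros((coef.shape[0], 1, km1)), coef], axis=1)
        z += full[:, codes, :].transpose(1, 0, 2)
    for name in eff.fixed_continuous:
        vals = np.asarray(np.atleast_1d(cov[name]), dtype=float)
        lo, hi = design.covariate_range[name]
        if not allow_extrapolation and (vals.min() < lo or vals.max() > hi):
            raise ValueError(
                f"covariate {name!r} values outside the observed range [{lo}, {hi}]; "
                "pass allow_extrapolation=True to override"
            )
        x = design.standardize(name, vals)  # (G,)
        beta = draws.stacked(f"cont:{name}")  # (S, K-1)
        z += x[:, None, None] * beta[None, :, :]
    if include_random:
        for name in eff.random:
            if name not in cov:
                continue
            labels = [str(v) for v in np.atleast_1d(cov[name])]
            codes = design.level_codes(name, labels)
            off = draws.stacked(f"ranef:{name}")  # (S, L, K-1)
            z += off[:, codes, :].transpose(1, 0, 2)

    basis = ilr_basis(km1 + 1)
    y = z @ basis.T
    y -= y.max(axis=-1, keepdims=True)
    ey = np.exp(y)
    p = ey / ey.sum(axis=-1, keepdims=True)  # (G, S, K)

    summary = {}
    for k, src in enumerate(draws.source_names):
        qs = np.quantile(p[:, :, k], quantiles, axis=1)
        summary[src] = pd.DataFrame(
            {f"q{q:g}": qs[i] for i, q in enumerate(quantiles)}
        )
    eps = specialization_index(p)
    return {
        "p_draws": p,
        "epsilon_draws": eps,
        "summary": summary,
        "epsilon_summary": pd.DataFrame(
            {f"q{q:g}": np.quantile(eps, q, axis=1) for q in quantiles}
        ),
    }


# ---------------------------------------------------------------------------
# mixing polygon diagnostic
# ---------------------------------------------------------------------------


def _convex_hull(points: np.ndarray) -> np.ndarray:
    """Andrew's monotone chain; returns hull vertices in CCW order."""
    pts = np.unique(points, axis=0)
    if pts.shape[0] <= 2:
        return pts
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list[np.ndarray] = []
    for pt in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], pt) <= 0:
            lower.pop()
        lower.append(pt)
    upper: list[np.ndarray] = []
    for pt in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], pt) <= 0:
            upper.pop()
        upper.append(pt)
    return np.array(lower[:-1] + upper[:-1])


def _shoelace(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _inside_hull(point: np.ndarray, hull: np.ndarray) -> bool:
    """Orientation test against each CCW edge; boundary counts as inside."""
    n = hull.shape[0]
    for i in range(n):
        a, b = hull[i], hull[(i + 1) % n]
        cross = (b[0] - a[0]) * (point[1] - a[1]) - (b[1] - a[1]) * (point[0] - a[0])
        if cross < 0:
            return False
    return True


def calc_area(
    sources: SourceData,
    discrimination: DiscriminationData,
    mixture: MixtureData,
) -> dict:
    """Mixing-polygon diagnostic for 2-tracer systems.

    Convex-hull (shoelace) area of the discrimination-corrected source
    means in tracer space, plus the fraction of mixture points inside
    the hull (boundary counts as inside).  Consumers outside the polygon
    cannot be written as a convex combination of the source means and
    signal model misspecification.
    """
    if sources.n_tracers != 2 or mixture.n_tracers != 2:
        raise ValueError("calc_area supports exactly 2 tracers")
    corrected = sources.means + discrimination.means  # (K, 2)
    hull = _convex_hull(corrected)
    degenerate = hull.shape[0] < 3
    if degenerate:
        warnings.warn("source polygon is degenerate (collinear or <3 distinct sources)")
        area = 0.0
        inside = np.zeros(mixture.n, dtype=bool)
    else:
        area = _shoelace(hull)
        inside = np.array([_inside_hull(pt, hull) for pt in mixture.values])
    return {
        "area": float(area),
        "inside_fraction": float(inside.mean()),
        "inside": inside,
        "hull": hull,
        "degenerate": degenerate,
    }
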