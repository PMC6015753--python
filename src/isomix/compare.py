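"""WAIC and PSIS-LOO from pointwise log likelihoods, and the relative
support table (LOOic, dLOOic, Akaike weights) for a set of candidate
models fit to the same mixture data.

The pointwise matrix contains one joint term per consumer (mixture
observations only; source-data terms are excluded), so "leave one out"
means leaving out one consumer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["WaicResult", "LooResult", "waic", "psis_loo", "compare_models"]


@dataclass
class WaicResult:
    waic: float
    se: float
    p_waic: float
    elpd_pointwise: np.ndarray

    def __iter__(self):
        return iter((self.waic, self.se, self.p_waic))


@dataclass
class LooResult:
    looic: float
    se: float
    pareto_k: np.ndarray
    elpd_pointwise: np.ndarray
    p_loo: float

    def __iter__(self):
        return iter((self.looic, self.se, self.pareto_k))


def _as_matrix(pointwise_loglik: np.ndarray) -> np.ndarray:
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim == 3:  # (chains, draws, N)
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2:
        raise ValueError("pointwise log likelihood must be draws x observations")
    if ll.shape[0] < 2:
        raise ValueError("need at least 2 posterior draws")
    if not np.all(np.isfinite(ll)):
        bad = sorted(set(np.nonzero(~np.isfinite(ll))[1].tolist()))
        raise ValueError(f"non-finite log likelihood for observation(s) {bad}")
    return ll


def waic(pointwise_loglik: np.ndarray) -> WaicResult:
    """Widely applicable information criterion.

    elpd_i = log mean_s exp(ll_si) - var_s(ll_si);  waic = -2 sum_i elpd_i.
    The SE comes from the observation-level variance of the pointwise
    contributions.
    """
    ll = _as_matrix(pointwise_loglik)
    s, n = ll.shape
    lpd = logsumexp(ll, axis=0) - np.log(s)
    p_waic = ll.var(axis=0, ddof=1)
    elpd_i = lpd - p_waic
    w = -2.0 * elpd_i.sum()
    se = 2.0 * float(np.sqrt(n * elpd_i.var(ddof=1))) if n > 1 else 0.0
    return WaicResult(waic=float(w), se=se, p_waic=float(p_waic.sum()), elpd_pointwise=elpd_i)


# ---------------------------------------------------------------------------
# Pareto-smoothed importance sampling
# ---------------------------------------------------------------------------


def _gpd_fit(x: np.ndarray) -> tuple[float, float]:
    """Fit a generalized Pareto to exceedances (Zhang & Stephens 2009).

    Returns (k, sigma) for the parameterization with cdf
    1 - (1 + k x / sigma)^(-1/k).
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    prior_bs, prior_k = 3.0, 10.0
    m = 30 + int(np.sqrt(n))
    b = 1.0 - np.sqrt(m / (np.arange(1, m + 1) - 0.5))
    b /= prior_bs * x[int(n / 4 + 0.5) - 1]
    b += 1.0 / x[-1]
    k = np.log1p(-b[:, None] * x[None, :]).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lik = n * (np.log(-b / k) - k - 1.0)
    log_lik[~np.isfinite(log_lik)] = -np.inf
    weights = np.exp(log_lik - log_lik.max())  # profile-likelihood softmax
    weights /= weights.sum()
    b_post = float((b * weights).sum())
    k_post = float(np.log1p(-b_post * x).mean())
    sigma = -k_post / b_post
    # weak prior pulling k toward 0.5 stabilizes small tails
    k_post = (n * k_post + prior_k * 0.5) / (n + prior_k)
    return k_post, sigma


def _gpd_quantiles(q: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-q)
    return sigma / k * (np.power(1.0 - q, -k) - 1.0)


def _psis_weights(log_ratios: np.ndarray) -> tuple[np.ndarray, float]:
    """Smooth one observation's log importance ratios; returns (lw, k_hat)."""
    s = log_ratios.size
    lw = log_ratios - log_ratios.max()
    n_tail = int(np.ceil(min(0.2 * s, 3.0 * np.sqrt(s))))
    if n_tail < 5:
        return lw, float("inf")
    order = np.argsort(lw)
    tail_idx = order[-n_tail:]
    cutoff = lw[order[-n_tail - 1]]
    exceed = np.exp(lw[tail_idx]) - np.exp(cutoff)
    if np.ptp(exceed) <= 0:
        return lw, float("inf")
    k, sigma = _gpd_fit(exceed)
    if np.isfinite(k):
        q = (np.arange(1, n_tail + 1) - 0.5) / n_tail
        smoothed = np.log(_gpd_quantiles(q, k, sigma) + np.exp(cutoff))
        ranks = np.argsort(lw[tail_idx])
        new_tail = np.empty(n_tail)
        new_tail[ranks] = smoothed
        lw = lw.copy()
        lw[tail_idx] = new_tail
    lw = np.minimum(lw, 0.0)  # truncate at the raw maximum
    return lw, float(k)


def psis_loo(pointwise_loglik: np.ndarray) -> LooResult:
    """Approximate leave-one-out via Pareto-smoothed importance sampling.

    looic = -2 * sum_i elpd_loo_i with per-observation Pareto shape
    diagnostics; k > 0.7 indicates an unreliable contribution.
    """
    ll = _as_matrix(pointwise_loglik)
    s, n = ll.shape
    elpd_i = np.empty(n)
    k_hat = np.empty(n)
    lpd = logsumexp(ll, axis=0) - np.log(s)
    for i in range(n):
        lw, k = _psis_weights(-ll[:, i])
        lw = lw - logsumexp(lw)
        elpd_i[i] = logsumexp(lw + ll[:, i])
        k_hat[i] = k
    looic = -2.0 * float(elpd_i.sum())
    se = 2.0 * float(np.sqrt(n * elpd_i.var(ddof=1))) if n > 1 else 0.0
    p_loo = float((lpd - elpd_i).sum())
    return LooResult(looic=looic, se=se, pareto_k=k_hat, elpd_pointwise=elpd_i, p_loo=p_loo)


# ---------------------------------------------------------------------------
# comparison table
# ---------------------------------------------------------------------------


def compare_models(fits: Mapping[str, "PosteriorDraws"]) -> pd.DataFrame:
    """Relative-support table: LOOic, SE, dLOOic, SE(dLOOic), Akaike weight.

    All fits must be to identical mixture data (enforced via the data
    hash stored at fit time).  Weights are
    exp(-dLOOic/2) / sum exp(-dLOOic/2), the estimated probability each
    model predicts best on new data.  Per-tracer xi posterior medians
    are appended when the model has a multiplicative error term.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fitted models to compare")
    hashes = {name: d.meta.get("data_hash") for name, d in fits.items()}
    if len(set(hashes.values())) > 1:
        raise ValueError(f"fits are not on identical mixture data: {hashes}")

    loos = {name: psis_loo(d.loglik) for name, d in fits.items()}
    best = min(loos, key=lambda m: loos[m].looic)
    rows = []
    for name, d in fits.items():
        res = loos[name]
        dloo = res.looic - loos[best].looic
        if name == best:
            se_d = np.nan
        else:
            diff = res.elpd_pointwise - loos[best].elpd_pointwise
            se_d = 2.0 * float(np.sqrt(diff.size * diff.var(ddof=1)))
        row = {
            "model": name,
            "LOOic": res.looic,
            "SE_LOOic": res.se,
            "dLOOic": dloo,
            "SE_dLOOic": se_d,
            "max_pareto_k": float(res.pareto_k.max()),
        }
        if "xi" in d.params:
            xi_med = np.median(d.stacked("xi"), axis=0)
            for j, tr in enumerate(d.tracer_names):
                row[f"xi_median[{tr}]"] = float(xi_med[j])
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("LOOic").reset_index(drop=True)
    rel = np.exp(-0.5 * (df["LOOic"] - df["LOOic"].min()))
    df.insert(5, "weight", rel / rel.sum())
    return df


from isomix.inference import PosteriorDraws  # noqa: E402  (typing only)
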