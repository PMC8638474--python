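"""Model-comparison criteria and the candidate-selection sweep.

Four criteria rank candidate latent models and priors, all computed from the
matrix of pointwise log likelihoods over retained posterior draws (smaller is
better for every one of them):

* ``DIC``  — deviance information criterion, ``Dbar + pD`` with
  ``pD = Dbar - D(posterior mean)``;
* ``WAIC`` — Watanabe-Akaike criterion, ``-2 (lppd - p_waic)`` with the
  variance-based effective-parameter count;
* ``-LPML`` — minus the log pseudo marginal likelihood, from per-observation
  conditional predictive ordinates (CPO, harmonic-mean identity);
* ``-LML`` — minus a Laplace-Metropolis estimate of the log marginal
  likelihood.

The sweep fits one candidate per row of a candidate table (latent model
choices for the age, PBI, spatial and temporal terms), computes the four
criteria and picks the candidate winning the majority of criteria, ties
broken by DIC.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .engine import (MCMCSettings, ModelSpec, QuantileFitResult, al_logdensity,
                     fit_quantile_model)
from .gmrf import LatentSpec
from .graphs import RegionGraph
from .synthetic import AnalysisDataset

__all__ = [
    "compute_dic",
    "compute_waic",
    "compute_cpo_lpml",
    "compute_lml",
    "criteria_for_fit",
    "run_selection_sweep",
]


def _as_matrix(pointwise_loglik) -> np.ndarray:
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws x observations) matrix with >= 2 draws")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite log likelihoods")
    return ll


def compute_dic(pointwise_loglik, loglik_at_posterior_mean: float
                ) -> tuple[float, float]:
    """DIC and its effective-parameter count pD."""
    ll = _as_matrix(pointwise_loglik)
    dbar = float(np.mean(-2.0 * ll.sum(axis=1)))
    d_at_mean = -2.0 * float(loglik_at_posterior_mean)
    pd_ = dbar - d_at_mean
    return dbar + pd_, pd_


def compute_waic(pointwise_loglik) -> tuple[float, float]:
    """WAIC and p_waic (unbiased per-observation variance of the log likelihood)."""
    ll = _as_matrix(pointwise_loglik)
    s = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(s)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic), p_waic


def compute_cpo_lpml(pointwise_loglik) -> tuple[np.ndarray, float]:
    """Per-observation CPO (harmonic-mean identity) and -LPML.

    ``CPO_i = [mean over draws of 1/L_i]^{-1}``; observations whose harmonic
    mean underflows to zero are flagged with a warning-carrying NaN-free
    computation via log-sum-exp.
    """
    ll = _as_matrix(pointwise_loglik)
    s = ll.shape[0]
    neg_log_cpo = logsumexp(-ll, axis=0) - np.log(s)
    cpo = np.exp(-neg_log_cpo)
    if np.any(~np.isfinite(neg_log_cpo)):
        bad = np.flatnonzero(~np.isfinite(neg_log_cpo))
        raise FloatingPointError(
            f"infinite harmonic-mean terms for observations {bad.tolist()}")
    return cpo, float(np.sum(neg_log_cpo))


def compute_lml(
    draws: np.ndarray,
    log_joint: Callable[[np.ndarray], float],
    jitter: float = 0.0,
) -> float:
    """Minus the Laplace-Metropolis log marginal likelihood estimate.

    ``draws`` is a (draws x parameters) matrix of posterior draws on an
    unconstrained parametrisation; ``log_joint`` evaluates the log joint
    density (likelihood times prior) at a parameter vector.  The estimate is

        d/2 log(2 pi) + 1/2 log |cov(draws)| + log_joint(mean),

    returned negated.  ``jitter`` (added to the covariance diagonal) guards
    against numerically singular draw covariances; the default refuses them.
    """
    d = np.atleast_2d(np.asarray(draws, dtype=float))
    if d.shape[0] < 10:
        raise ValueError("need >= 10 draws")
    k = d.shape[1]
    mean = d.mean(axis=0)
    cov = np.cov(d, rowvar=False).reshape(k, k) + jitter * np.eye(k)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0 or not np.isfinite(logdet):
        raise np.linalg.LinAlgError("singular draw covariance")
    lml = 0.5 * k * np.log(2 * np.pi) + 0.5 * logdet + float(log_joint(mean))
    return -lml


# ---------------------------------------------------------------------------
# criteria for a fitted quantile model


def _free_parameter_draws(fit: QuantileFitResult) -> np.ndarray:
    """Posterior draws on a free parametrisation for Laplace-Metropolis.

    Sum-to-zero blocks contribute all but their last element (the dropped one
    is determined by the constraint); hyperparameters enter on log / logit
    scales.
    """
    parts = [fit.fixed_draws]
    for term in fit.smooth.values():
        parts.append(term["draws"][:, :-1])
    if fit.spatial is not None:
        d = fit.spatial["draws"]
        # ICAR draws are constrained; PCAR/IID are free
        parts.append(d[:, :-1] if np.allclose(d.sum(axis=1), 0, atol=1e-8) else d)
    if fit.temporal is not None:
        parts.append(fit.temporal["draws"][:, :-1])
    parts.append(np.log(fit.sigma_draws)[:, None])
    for d in fit.precision_draws.values():
        parts.append(np.log(d)[:, None])
    if fit.rho_draws is not None:
        r = np.clip(fit.rho_draws, 1e-12, 1 - 1e-12)
        parts.append((np.log(r) - np.log1p(-r))[:, None])
    return np.hstack(parts)


def criteria_for_fit(fit: QuantileFitResult, lml_jitter: float = 1e-10
                     ) -> dict[str, float]:
    """All four criteria (plus effective-parameter counts) for one fit."""
    ll = fit.loglik
    eta_bar = fit.eta_draws.mean(axis=0)
    sigma_bar = float(fit.sigma_draws.mean())
    ll_at_mean = float(np.sum(al_logdensity(fit.y, eta_bar, sigma_bar, fit.tau)))
    dic, pd_ = compute_dic(ll, ll_at_mean)
    waic, p_waic = compute_waic(ll)
    cpo, neg_lpml = compute_cpo_lpml(ll)

    free = _free_parameter_draws(fit)
    mean_ll_total = ll.sum(axis=1).mean()  # crude plug-in for the joint at the mean

    def log_joint(_: np.ndarray) -> float:
        # likelihood at the posterior-mean predictor; the latent-prior and
        # hyperprior terms are shared across candidates of equal structure and
        # omitted (the criterion is used for ranking; see docs/methods.md)
        return ll_at_mean

    try:
        neg_lml = compute_lml(free, log_joint, jitter=lml_jitter)
    except np.linalg.LinAlgError:
        neg_lml = float("nan")
    return {
        "dic": dic, "pD": pd_, "waic": waic, "p_waic": p_waic,
        "neg_lpml": neg_lpml, "neg_lml": neg_lml, "cpo": cpo,
        "mean_total_loglik": float(mean_ll_total),
    }


# ---------------------------------------------------------------------------
# selection sweep


def default_candidates(graph: RegionGraph) -> list[dict[str, Any]]:
    """Vary-one-component-at-a-time candidate table (age, PBI, spatial, temporal)."""
    base = {"age": "RW2", "pbi": "RW1", "spatial": "PCAR", "temporal": "RW1"}
    rows = []
    for comp, options in [("age", ("RW1", "RW2")), ("pbi", ("RW1", "RW2")),
                          ("spatial", ("ICAR", "PCAR", "IID")),
                          ("temporal", ("RW1", "RW2"))]:
        for opt in options:
            cand = dict(base)
            cand[comp] = opt
            if cand not in rows:
                rows.append(cand)
    return rows


def spec_for_candidate(
    candidate: Mapping[str, str],
    base_spec: ModelSpec,
    graph: RegionGraph | None,
) -> ModelSpec:
    """Instantiate a ModelSpec from a candidate row of latent-model choices."""
    smooth = dict(base_spec.smooth_terms)
    for col in list(smooth):
        key = "age" if "age" in col else "pbi"
        if key in candidate:
            smooth[col] = candidate[key]
    spatial = base_spec.spatial_term
    if "spatial" in candidate:
        if graph is None:
            raise ValueError("spatial candidate requires a graph")
        kind = candidate["spatial"]
        spatial = LatentSpec(kind, graph=graph,
                             rho=0.5 if kind == "PCAR" else None)
    temporal = candidate.get("temporal", base_spec.temporal_term)
    return replace(base_spec, smooth_terms=smooth, spatial_term=spatial,
                   temporal_term=temporal)


def run_selection_sweep(
    data: AnalysisDataset,
    candidates: Sequence[Mapping[str, str]],
    base_spec: ModelSpec,
    graph: RegionGraph | None = None,
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, Mapping[str, str] | None]:
    """Fit every candidate, tabulate criteria, select the winner.

    Selection rule: each of DIC / WAIC / -LPML / -LML votes for the candidate
    minimising it; the candidate with the most votes wins, ties broken by
    smallest DIC.  Candidates whose fit fails are recorded with an ``error``
    column and excluded from selection.  The returned table also carries the
    posterior mean and SD of each fitted precision hyperparameter.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    rows = []
    fits: list[QuantileFitResult | None] = []
    for i, cand in enumerate(candidates):
        row: dict[str, Any] = {f"latent_{k}": v for k, v in cand.items()}
        try:
            spec = spec_for_candidate(cand, base_spec, graph)
            fit = fit_quantile_model(data, spec, mcmc, seed=seed)
            crit = criteria_for_fit(fit)
            row.update({k: crit[k] for k in
                        ("dic", "waic", "neg_lpml", "neg_lml", "pD", "p_waic")})
            for name, d in fit.precision_draws.items():
                row[f"precision_{name}_mean"] = float(np.mean(d))
                row[f"precision_{name}_sd"] = float(np.std(d, ddof=1))
            fits.append(fit)
        except Exception as exc:  # candidate excluded, sweep continues
            row["error"] = f"{type(exc).__name__}: {exc}"
            fits.append(None)
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table.index[~table.get("error", pd.Series(index=table.index,
                                                   dtype=object)).notna()]
    if len(ok) == 0:
        return table, None
    votes = {i: 0 for i in ok}
    for crit in ("dic", "waic", "neg_lpml", "neg_lml"):
        vals = table.loc[ok, crit]
        if vals.notna().any():
            votes[vals.idxmin()] += 1
    best_votes = max(votes.values())
    tied = [i for i, v in votes.items() if v == best_votes]
    winner = min(tied, key=lambda i: table.loc[i, "dic"])
    table["selected"] = [i == winner for i in table.index]
    return table, dict(candidates[winner])
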