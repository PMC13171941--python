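"""Posterior post-processing: inclusion probabilities, median model,
selection metrics, model-conditional summaries, and LOO predictive scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .baselines import ModelId
from .data import SelectionData
from .gibbs import PosteriorChain
from .model_core import log_likelihood

__all__ = [
    "SelectionMetrics",
    "ElpdResult",
    "pip",
    "median_model",
    "selection_metrics",
    "model_frequencies",
    "conditional_posterior",
    "pointwise_log_likelihood",
    "loo_elpd",
]


@dataclass
class SelectionMetrics:
    """Variable-selection performance of one selected model against truth.

    tpr: proportion of active variables correctly identified (sensitivity);
    tnr: proportion of inactive variables correctly identified (specificity);
    tmr: 1 iff the selected model is exactly the true model;
    model sizes per equation.
    """

    tpr: float
    tnr: float
    tmr: int
    model_size_out: int
    model_size_sel: int


@dataclass
class ElpdResult:
    """Leave-one-out expected log pointwise predictive density."""

    elpd: float
    pointwise: np.ndarray
    pareto_k: np.ndarray
    n_draws: int


def _check_nonempty(chain: PosteriorChain) -> None:
    if chain.n_draws == 0:
        raise ValueError("empty chain")


def pip(chain: PosteriorChain) -> tuple[np.ndarray, np.ndarray]:
    """Posterior inclusion probabilities (outcome, selection).

    The PIP of a variable is the fraction of stored draws in which its
    indicator equals one.
    """
    _check_nonempty(chain)
    return chain.gamma_out.mean(axis=0), chain.gamma_sel.mean(axis=0)


def median_model(chain: PosteriorChain) -> ModelId:
    """Median probability model: include iff PIP strictly greater than 0.5."""
    pip_out, pip_sel = pip(chain)
    return ModelId(tuple((pip_out > 0.5).astype(int)), tuple((pip_sel > 0.5).astype(int)))


def selection_metrics(selected: ModelId, truth: ModelId) -> SelectionMetrics:
    """Confusion summary of a selected model over the concatenated p + q slots."""
    if len(selected.outcome) != len(truth.outcome) or len(selected.selection) != len(
        truth.selection
    ):
        raise ValueError("model dimensions do not match")
    sel = np.array(selected.outcome + selected.selection)
    tru = np.array(truth.outcome + truth.selection)
    active = tru == 1
    tpr = float(sel[active].mean()) if active.any() else np.nan
    tnr = float((1 - sel[~active]).mean()) if (~active).any() else np.nan
    return SelectionMetrics(
        tpr=tpr, tnr=tnr, tmr=int(selected == truth),
        model_size_out=selected.size_outcome,
        model_size_sel=selected.size_selection,
    )


def _model_ids(chain: PosteriorChain) -> list[ModelId]:
    return [
        ModelId(tuple(go), tuple(gs))
        for go, gs in zip(chain.gamma_out, chain.gamma_sel)
    ]


def model_frequencies(chain: PosteriorChain, top_k: int = 10):
    """The ``top_k`` most visited (gamma_out, gamma_sel) configurations.

    Returns a list of ``(ModelId, frequency)`` sorted by decreasing visit
    frequency; frequencies over all visited models sum to one.
    """
    _check_nonempty(chain)
    counts: dict[ModelId, int] = {}
    for mid in _model_ids(chain):
        counts[mid] = counts.get(mid, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0].outcome, kv[0].selection))
    return [(mid, c / chain.n_draws) for mid, c in ranked[:top_k]]


def _model_draw_index(chain: PosteriorChain, model: ModelId) -> np.ndarray:
    go = np.array(model.outcome, dtype=chain.gamma_out.dtype)
    gs = np.array(model.selection, dtype=chain.gamma_sel.dtype)
    return np.flatnonzero(
        (chain.gamma_out == go).all(axis=1) & (chain.gamma_sel == gs).all(axis=1)
    )


def conditional_posterior(chain: PosteriorChain, model: ModelId) -> pd.DataFrame:
    """Posterior summaries conditional on one sampled model.

    Medians, standard deviations and central 95% intervals are computed only
    over iterations whose sampled configuration equals ``model``, and only
    for coefficients included in it (plus intercepts, sigma and rho).  A
    never-visited model gives an empty frame with ``attrs['count'] == 0``.
    """
    idx = _model_draw_index(chain, model)
    rows = []
    if idx.size:
        def _summ(name, draws):
            lo, hi = np.quantile(draws, [0.025, 0.975])
            rows.append(
                {"parameter": name, "median": float(np.median(draws)),
                 "sd": float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0,
                 "q2.5": float(lo), "q97.5": float(hi)}
            )

        _summ("alpha0", chain.alpha0[idx])
        for k, g in enumerate(model.selection):
            if g:
                _summ(f"alpha{k + 1}", chain.alpha[idx, k])
        _summ("beta0", chain.beta0[idx])
        for j, g in enumerate(model.outcome):
            if g:
                _summ(f"beta{j + 1}", chain.beta[idx, j])
        _summ("sigma", chain.sigma[idx])
        _summ("rho", chain.rho[idx])
    out = pd.DataFrame(rows, columns=["parameter", "median", "sd", "q2.5", "q97.5"])
    out.attrs["count"] = int(idx.size)
    return out


def pointwise_log_likelihood(
    chain: PosteriorChain, data: SelectionData, idx: np.ndarray | None = None
) -> np.ndarray:
    """(draws, units) matrix of per-unit observed-data log likelihoods.

    Selected units contribute the bivariate selection-outcome term; censored
    units contribute log Phi(-alpha0 - w'alpha).
    """
    from scipy.special import log_ndtr

    idx = np.arange(chain.n_draws) if idx is None else idx
    sel = data.observed_mask
    n1 = int(sel.sum())
    W = data.selection_covariates
    X1 = data.outcome_covariates[sel]
    y1 = data.outcome[sel]
    out = np.empty((idx.size, data.n))
    for row, t in enumerate(idx):
        p = chain.params_at(int(t))
        u = p.alpha0 + W @ p.alpha
        out[row, ~sel] = log_ndtr(-u[~sel])
        if n1:
            sigma, rho = p.sigma, p.rho
            z = (y1 - p.beta0 - X1 @ p.beta) / sigma
            tt = (u[sel] + rho * z) / np.sqrt(1.0 - rho**2)
            out[row, sel] = (
                log_ndtr(tt) - 0.5 * z**2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
            )
    return out


def loo_elpd(
    chain: PosteriorChain,
    model: ModelId,
    data: SelectionData,
    min_draws: int = 100,
) -> ElpdResult:
    """Model-conditional LOO elpd by Pareto-smoothed importance sampling.

    Uses only the draws whose sampled configuration equals ``model``.
    Importance weights 1/p(unit_i | theta_s) are stabilized by PSIS
    (``arviz.psislw``); per-unit tail-shape diagnostics are reported.  With a
    single draw the weights degenerate and the result is the plug-in sum of
    per-unit log likelihoods.
    """
    idx = _model_draw_index(chain, model)
    if idx.size < min_draws:
        raise ValueError(
            f"model visited {idx.size} times; at least {min_draws} draws required"
        )
    ll = pointwise_log_likelihood(chain, data, idx)
    if idx.size == 1:
        pointwise = ll[0]
        return ElpdResult(float(pointwise.sum()), pointwise, np.zeros(data.n), 1)
    from arviz import psislw

    lw, k = psislw(-ll.T)  # arviz expects (units, draws) here
    lw = np.asarray(lw)
    pointwise = logsumexp(lw + ll.T, axis=1)
    return ElpdResult(float(pointwise.sum()), pointwise, np.asarray(k), int(idx.size))
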