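"""Model/Results front end.

Two model classes cover the package's workflows:

* :class:`HeckmanModel` — the classical bivariate-normal sample selection
  model; ``fit()`` maximizes the likelihood, ``fit_two_step()`` runs
  Heckman's two-step estimator, and ``select_stepwise()`` performs forward
  selection by BIC.
* :class:`SpikeSlabSelectionModel` — the same likelihood under spike-and-slab
  priors on both equations; ``fit()`` runs the closed-form Gibbs sampler and
  returns a results object exposing posterior inclusion probabilities, the
  median probability model, model-conditional summaries and LOO scores.

Both accept a :class:`~heckselect.data.SelectionData` directly or a pandas
DataFrame through ``from_dataframe``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import baselines, gibbs, summaries
from .baselines import FitResult, ModelId
from .data import SelectionData
from .priors import SpikeSlabSpec, default_spec

__all__ = [
    "HeckmanModel",
    "HeckmanResults",
    "SpikeSlabSelectionModel",
    "SpikeSlabResults",
]


def _data_from_dataframe(df, outcome, selected, outcome_covariates,
                         selection_covariates, standardize):
    y = pd.to_numeric(df[outcome], errors="raise").to_numpy(dtype=float)
    data = SelectionData(
        y, df[selected].to_numpy(),
        df[list(outcome_covariates)].to_numpy(dtype=float),
        df[list(selection_covariates)].to_numpy(dtype=float),
        list(outcome_covariates), list(selection_covariates),
    )
    if standardize:
        data, record = data.standardized()
        return data, record
    return data, None


class HeckmanModel:
    """Classical sample selection model on a fixed dataset."""

    def __init__(self, data: SelectionData):
        self.data = data

    @classmethod
    def from_dataframe(cls, df, *, outcome, selected, outcome_covariates,
                       selection_covariates, standardize=False):
        data, record = _data_from_dataframe(
            df, outcome, selected, outcome_covariates, selection_covariates,
            standardize,
        )
        model = cls(data)
        model.standardization = record
        return model

    def loglike(self, params):
        from .model_core import log_likelihood

        return log_likelihood(params, self.data)

    def fit(self, model: ModelId | None = None, start=None) -> "HeckmanResults":
        """Maximum likelihood over the (optionally masked) parameter set."""
        return HeckmanResults(self, baselines.mle_fit(self.data, model, start))

    def fit_two_step(self) -> "HeckmanResults":
        """Heckman's two-step estimator (probit, then IMR-augmented OLS)."""
        return HeckmanResults(self, baselines.heckman_two_step(self.data))

    def select_stepwise(self, max_steps=None):
        """Forward selection by BIC; returns ``(HeckmanResults, trace)``."""
        model_id, trace = baselines.forward_stepwise(self.data, max_steps)
        final = baselines.mle_fit(self.data, model_id, start=trace[-1][1].params)
        return HeckmanResults(self, final), trace


class HeckmanResults:
    """Estimates, standard errors and diagnostics of a frequentist fit."""

    def __init__(self, model: HeckmanModel, fit: FitResult):
        self.model = model
        self._fit = fit

    @property
    def params(self):
        return self._fit.params

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def llf(self) -> float:
        return self._fit.llf

    @property
    def delta(self):
        return self._fit.delta

    @property
    def model_id(self) -> ModelId:
        return self._fit.model

    def bic(self) -> float:
        return self._fit.bic(self.model.data.n)

    def summary(self) -> pd.DataFrame:
        """Coefficient table: estimate and, when available, standard error."""
        fit = self._fit
        data = self.model.data
        rows = [("alpha0", fit.params.alpha0, fit.bse_alpha0)]
        for k, name in enumerate(data.selection_names):
            se = fit.bse_alpha[k] if fit.bse_alpha is not None else None
            rows.append((f"select:{name}", fit.params.alpha[k], se))
        rows.append(("beta0", fit.params.beta0, fit.bse_beta0))
        for j, name in enumerate(data.outcome_names):
            se = fit.bse_beta[j] if fit.bse_beta is not None else None
            rows.append((f"outcome:{name}", fit.params.beta[j], se))
        rows.append(("sigma", fit.params.sigma, None))
        rows.append(("rho", fit.params.rho, None))
        if fit.delta is not None:
            rows.append(("delta(IMR)", fit.delta, fit.delta_se))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se"])


class SpikeSlabSelectionModel:
    """Bayesian variable selection for the sample selection model.

    Parameters
    ----------
    data : SelectionData
    prior : SpikeSlabSpec, optional
        Defaults to the package elicitation (:func:`~heckselect.priors.default_spec`)
        at this dataset's dimensions.
    """

    def __init__(self, data: SelectionData, prior: SpikeSlabSpec | None = None):
        self.data = data
        self.prior = prior if prior is not None else default_spec(
            data.n, data.n_outcome_covariates, data.n_selection_covariates
        )

    @classmethod
    def from_dataframe(cls, df, *, outcome, selected, outcome_covariates,
                       selection_covariates, prior=None, standardize=True):
        data, record = _data_from_dataframe(
            df, outcome, selected, outcome_covariates, selection_covariates,
            standardize,
        )
        model = cls(data, prior)
        model.standardization = record
        return model

    def fit(self, n_iter=10_000, burn_in=1_250, thin=1, seed=0,
            init="mle") -> "SpikeSlabResults":
        """Run the Gibbs sampler and wrap the stored chain."""
        config = gibbs.GibbsConfig(
            n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed, init=init
        )
        chain = gibbs.run_chain(self.data, self.prior, config)
        return SpikeSlabResults(self, chain)


class SpikeSlabResults:
    """Posterior chain with selection-oriented summaries."""

    def __init__(self, model: SpikeSlabSelectionModel, chain: gibbs.PosteriorChain):
        self.model = model
        self.chain = chain

    @property
    def pips(self) -> tuple[np.ndarray, np.ndarray]:
        """(outcome, selection) posterior inclusion probabilities."""
        return summaries.pip(self.chain)

    @property
    def median_model(self) -> ModelId:
        return summaries.median_model(self.chain)

    def metrics(self, truth: ModelId) -> summaries.SelectionMetrics:
        return summaries.selection_metrics(self.median_model, truth)

    def model_frequencies(self, top_k=10):
        return summaries.model_frequencies(self.chain, top_k)

    def conditional(self, model: ModelId) -> pd.DataFrame:
        return summaries.conditional_posterior(self.chain, model)

    def loo(self, model: ModelId, min_draws=100) -> summaries.ElpdResult:
        return summaries.loo_elpd(self.chain, model, self.model.data, min_draws)

    def summary(self) -> pd.DataFrame:
        """PIP / posterior-median / posterior-SD table for every variable."""
        data = self.model.data
        pip_out, pip_sel = self.pips
        rows = [
            {"parameter": "alpha0", "pip": np.nan,
             "estimate": float(np.median(self.chain.alpha0)),
             "sd": float(self.chain.alpha0.std(ddof=1))}
        ]
        for k, name in enumerate(data.selection_names):
            rows.append(
                {"parameter": f"select:{name}", "pip": float(pip_sel[k]),
                 "estimate": float(np.median(self.chain.alpha[:, k])),
                 "sd": float(self.chain.alpha[:, k].std(ddof=1))}
            )
        rows.append(
            {"parameter": "beta0", "pip": np.nan,
             "estimate": float(np.median(self.chain.beta0)),
             "sd": float(self.chain.beta0.std(ddof=1))}
        )
        for j, name in enumerate(data.outcome_names):
            rows.append(
                {"parameter": f"outcome:{name}", "pip": float(pip_out[j]),
                 "estimate": float(np.median(self.chain.beta[:, j])),
                 "sd": float(self.chain.beta[:, j].std(ddof=1))}
            )
        for name, draws in (("sigma", self.chain.sigma), ("rho", self.chain.rho)):
            rows.append(
                {"parameter": name, "pip": np.nan,
                 "estimate": float(np.median(draws)),
                 "sd": float(draws.std(ddof=1))}
            )
        return pd.DataFrame(rows, columns=["parameter", "pip", "estimate", "sd"])

    def plot_trace(self, params=("rho", "sigma"), axes=None):
        """Quick trace plots of derived scalar parameters."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(len(params), 1, squeeze=False)
            axes = axes[:, 0]
        for ax, name in zip(axes, params):
            ax.plot(getattr(self.chain, name), lw=0.5)
            ax.set_ylabel(name)
        return axes
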