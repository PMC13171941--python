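"""Synthetic-data generator for the sparse sample-selection study design.

Covariates are AR(1)-correlated standard normals (corr(w_j, w_k) =
decay^{|j-k|}), shared by both equations (no exclusion restriction).  Three
active coefficients per equation represent a small, medium and large effect:
alpha = (0.5, 1, 1.5, 0, ..., 0)/sqrt(2) and beta = (0.25, 0.5, 1, 0, ...,
0).  Errors are bivariate normal with Var(e1) = sigma^2, Var(e2) = 1 and
correlation rho.  The selection intercept is calibrated on the realized
covariate matrix so the expected missingness equals a target (default 30%).

Replicates within a scenario keep the covariates fixed and redraw only the
errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .baselines import ModelId
from .data import SelectionData
from .model_core import ModelParams

__all__ = ["SimScenario", "ar1_covariates", "calibrate_intercept", "simulate",
           "simulate_given_covariates"]

_DEFAULT_ALPHA = tuple(a / math.sqrt(2.0) for a in (0.5, 1.0, 1.5))
_DEFAULT_BETA = (0.25, 0.5, 1.0)


@dataclass
class SimScenario:
    """Generating truth for one simulation scenario."""

    n: int = 500
    p: int = 10
    q: int = 10
    rho: float = 0.5
    sigma: float = 1.0
    beta0: float = 0.5
    alpha_active: tuple = _DEFAULT_ALPHA
    beta_active: tuple = _DEFAULT_BETA
    corr_decay: float = 0.5
    target_missing: float = 0.3
    shared_covariates: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (-1, 1)")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.corr_decay < 1.0:
            raise ValueError("corr_decay must lie in [0, 1)")
        if not 0.0 < self.target_missing < 1.0:
            raise ValueError("target_missing must lie in (0, 1)")
        if len(self.alpha_active) > self.q or len(self.beta_active) > self.p:
            raise ValueError("active coefficient vectors longer than p or q")

    @property
    def alpha(self) -> np.ndarray:
        out = np.zeros(self.q)
        out[: len(self.alpha_active)] = self.alpha_active
        return out

    @property
    def beta(self) -> np.ndarray:
        out = np.zeros(self.p)
        out[: len(self.beta_active)] = self.beta_active
        return out

    @property
    def true_model(self) -> ModelId:
        return ModelId(
            tuple((self.beta != 0).astype(int)),
            tuple((self.alpha != 0).astype(int)),
        )


def ar1_covariates(n: int, p: int, decay: float, rng: np.random.Generator):
    """n x p matrix of standard-normal columns with cov(w_j, w_k) = decay^|j-k|.

    Generated by the stationary AR(1) recursion across columns, which has
    exactly this covariance and unit marginal variances.
    """
    if not 0.0 <= decay < 1.0:
        raise ValueError("decay must lie in [0, 1)")
    z = rng.standard_normal((n, p))
    W = np.empty((n, p))
    W[:, 0] = z[:, 0]
    root = math.sqrt(1.0 - decay**2)
    for j in range(1, p):
        W[:, j] = decay * W[:, j - 1] + root * z[:, j]
    return W


def calibrate_intercept(alpha, W, target_missing: float) -> float:
    """Selection intercept solving mean_i Phi(a0 + w_i'alpha) = 1 - target.

    The empirical-average probit probability is strictly increasing in a0,
    so the root exists and is unique; solved by bracketed root-finding to
    1e-10.
    """
    if not 0.0 < target_missing < 1.0:
        raise ValueError("target_missing must lie in (0, 1)")
    eta = np.asarray(W) @ np.asarray(alpha)
    target = 1.0 - target_missing

    def f(a0):
        return float(np.mean(ndtr(a0 + eta))) - target

    lo, hi = float(ndtri(target)) - 1.0, float(ndtri(target)) + 1.0
    lo -= abs(eta).max() if eta.size else 0.0
    hi += abs(eta).max() if eta.size else 0.0
    return float(brentq(f, lo, hi, xtol=1e-10))


def simulate_given_covariates(
    scenario: SimScenario, W: np.ndarray, rng: np.random.Generator
):
    """One replicate on a fixed covariate matrix: redraw errors only.

    Returns ``(data, truth)`` where truth holds the generating
    :class:`ModelParams` (with the calibrated intercept), the true
    :class:`ModelId`, and the scenario echo.
    """
    W = np.asarray(W)
    n = W.shape[0]
    alpha, beta = scenario.alpha, scenario.beta
    alpha0 = calibrate_intercept(alpha, W, scenario.target_missing)
    X = W[:, : scenario.p] if scenario.shared_covariates else ar1_covariates(
        n, scenario.p, scenario.corr_decay, rng
    )
    e2 = rng.standard_normal(n)
    e1 = scenario.sigma * (
        scenario.rho * e2 + math.sqrt(1.0 - scenario.rho**2) * rng.standard_normal(n)
    )
    s_star = alpha0 + W @ alpha + e2
    y_star = scenario.beta0 + X @ beta + e1
    selected = (s_star > 0).astype(int)
    y = np.where(selected == 1, y_star, np.nan)
    data = SelectionData(y, selected, X, W)
    truth = {
        "params": ModelParams.from_natural(
            alpha0, alpha, scenario.beta0, beta, scenario.sigma, scenario.rho
        ),
        "model": scenario.true_model,
        "scenario": scenario,
        "alpha0": alpha0,
    }
    return data, truth


def simulate(scenario: SimScenario, rng: np.random.Generator | None = None):
    """Draw covariates, calibrate the intercept, and simulate one dataset."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    dim = max(scenario.p, scenario.q)
    W = ar1_covariates(scenario.n, dim, scenario.corr_decay, rng)[:, : scenario.q]
    return simulate_given_covariates(scenario, W, rng)
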