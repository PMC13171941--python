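"""Core algebra of the bivariate-normal sample selection (Heckman) model.

The model couples a latent outcome equation with a latent selection index,

    y*_i = beta0 + x_i' beta + e1_i        (outcome)
    s*_i = alpha0 + w_i' alpha + e2_i      (selection)

with (e1, e2) bivariate normal, Var(e1) = sigma^2, Var(e2) = 1 (the index
scale is not identified), Corr = rho.  The outcome is observed iff s*_i > 0.

The module stores error scales in the reparametrization

    rho_tilde = rho * sigma          (error covariance)
    sigma_tilde_sq = sigma^2 (1 - rho^2)   (conditional outcome variance)

under which all Gibbs full conditionals are conjugate; the natural
(sigma, rho) pair is always derived, never stored.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr

from .data import SelectionData

__all__ = [
    "ModelParams",
    "GaussianSpec",
    "LatentConditional",
    "inverse_mills",
    "kappa",
    "selected_moments",
    "log_likelihood",
    "latent_conditional",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _log_norm_pdf(z):
    return -0.5 * np.square(z) - _LOG_SQRT_2PI


def inverse_mills(u):
    """Inverse Mills ratio lambda(u) = phi(u) / Phi(u).

    Equals the mean of a standard normal truncated to {Z > -u}; strictly
    positive and strictly decreasing.  Evaluated as exp(log phi - log Phi);
    ``log_ndtr`` switches to a scaled-erfc expansion in the lower tail, so
    the ratio is accurate for arguments down to (at least) -40.
    """
    u = np.asarray(u, dtype=float)
    if not np.isfinite(u).all():
        raise ValueError("inverse_mills requires finite input")
    out = np.exp(_log_norm_pdf(u) - log_ndtr(u))
    return out if out.ndim else float(out)


def kappa(u):
    """kappa(u) = lambda(u) {lambda(u) + u}, strictly inside (0, 1).

    One minus the variance of a standard normal truncated to {Z > -u}; it is
    the per-unit variance-reduction factor the selection process induces on
    the observed outcomes.
    """
    u = np.asarray(u, dtype=float)
    if not np.isfinite(u).all():
        raise ValueError("kappa requires finite input")
    lam = inverse_mills(u)
    out = lam * (lam + u)
    return out if np.ndim(out) else float(out)


@dataclass
class ModelParams:
    """Model parameters in the (rho_tilde, sigma_tilde_sq) parametrization.

    ``sigma_sq``, ``sigma`` and ``rho`` are derived accessors:
    sigma^2 = sigma_tilde^2 + rho_tilde^2 and rho = rho_tilde / sigma.
    """

    alpha0: float
    alpha: np.ndarray
    beta0: float
    beta: np.ndarray
    rho_tilde: float
    sigma_tilde_sq: float

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not self.sigma_tilde_sq > 0:
            raise ValueError("sigma_tilde_sq must be strictly positive")

    @property
    def sigma_sq(self) -> float:
        return self.sigma_tilde_sq + self.rho_tilde**2

    @property
    def sigma(self) -> float:
        return math.sqrt(self.sigma_sq)

    @property
    def rho(self) -> float:
        return self.rho_tilde / self.sigma

    @classmethod
    def from_natural(cls, alpha0, alpha, beta0, beta, sigma, rho) -> "ModelParams":
        """Build from the natural (sigma, rho) parametrization, |rho| < 1."""
        if not sigma > 0:
            raise ValueError("sigma must be positive")
        if not abs(rho) < 1:
            raise ValueError("rho must lie strictly inside (-1, 1)")
        return cls(
            alpha0=alpha0,
            alpha=alpha,
            beta0=beta0,
            beta=beta,
            rho_tilde=rho * sigma,
            sigma_tilde_sq=sigma**2 * (1.0 - rho**2),
        )

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.alpha0, self.alpha.copy(), self.beta0, self.beta.copy(),
            self.rho_tilde, self.sigma_tilde_sq,
        )


class Truncation(enum.Enum):
    """Support restriction of a univariate Gaussian."""

    NONE = "none"
    NEGATIVE = "(-inf,0)"
    POSITIVE = "(0,inf)"


@dataclass
class GaussianSpec:
    mean: float
    variance: float
    truncation: Truncation = Truncation.NONE

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError("variance must be positive")


class LatentConditional(enum.Enum):
    """Which latent-variable conditional law to return."""

    S_STAR_MARGINAL = "s_star_marginal"
    S_STAR_GIVEN_Y = "s_star_given_y"
    Y_STAR_GIVEN_S_STAR = "y_star_given_s_star"


def selected_moments(params: ModelParams, x, w):
    """Mean and variance of the outcome among selected units.

    mean = beta0 + x'beta + sigma rho lambda(u),
    variance = sigma^2 [1 - rho^2 kappa(u)],  u = alpha0 + w'alpha.

    The variance never exceeds sigma^2 (equality iff rho = 0): selection
    makes the observed data heteroscedastic and under-dispersed.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    u = params.alpha0 + w @ params.alpha
    mean = params.beta0 + x @ params.beta + params.sigma * params.rho * inverse_mills(u)
    variance = params.sigma_sq * (1.0 - params.rho**2 * kappa(u))
    return mean, variance


def log_likelihood(params: ModelParams, data: SelectionData) -> float:
    """Observed-data log-likelihood of the sample selection model.

    Sum of log Phi(-u_i) over non-selected units and, over selected units,
    log Phi((u_i + rho z_i)/sqrt(1-rho^2)) - z_i^2/2 - log sigma - log(2 pi)/2
    with z_i = (y_i - beta0 - x_i'beta)/sigma.  Tail-stable through
    ``log_ndtr``.
    """
    sigma = params.sigma
    u = params.alpha0 + data.selection_covariates @ params.alpha
    sel = data.observed_mask
    ll = float(np.sum(log_ndtr(-u[~sel])))
    if sel.any():
        z = (data.outcome[sel] - params.beta0 - data.outcome_covariates[sel] @ params.beta) / sigma
        # (u + rho z)/sqrt(1-rho^2) written via sigma_tilde = sigma
        # sqrt(1-rho^2): exact and stable even as |rho| -> 1
        sigma_tilde = math.sqrt(params.sigma_tilde_sq)
        t = (u[sel] * sigma + params.rho_tilde * z) / sigma_tilde
        ll += float(
            np.sum(log_ndtr(t) - 0.5 * z**2 - math.log(sigma) - _LOG_SQRT_2PI)
        )
    return ll


def score(params: ModelParams, data: SelectionData) -> dict:
    """Analytic gradient of :func:`log_likelihood`.

    Returned in natural coordinates as a dict with entries ``alpha0``,
    ``alpha``, ``beta0``, ``beta``, ``sigma``, ``rho``.  Used by the ML
    optimizer (chained into its unconstrained parametrization) and checked
    against central differences in the test suite.
    """
    sigma = params.sigma
    rho = params.rho
    root = math.sqrt(params.sigma_tilde_sq) / sigma  # sqrt(1 - rho^2), stable
    onem = root**2
    u = params.alpha0 + data.selection_covariates @ params.alpha
    sel = data.observed_mask
    W0, W1 = data.selection_covariates[~sel], data.selection_covariates[sel]
    X1 = data.outcome_covariates[sel]

    # non-selected: d/du log Phi(-u) = -lambda(-u)
    g_u0 = -inverse_mills(-u[~sel])
    d_alpha0 = float(np.sum(g_u0))
    d_alpha = W0.T @ g_u0

    d_beta0 = 0.0
    d_beta = np.zeros(data.n_outcome_covariates)
    d_sigma = 0.0
    d_rho = 0.0
    if sel.any():
        z = (data.outcome[sel] - params.beta0 - X1 @ params.beta) / sigma
        t = (u[sel] * sigma + params.rho_tilde * z) / math.sqrt(params.sigma_tilde_sq)
        lam_t = inverse_mills(t)
        g_u1 = lam_t / root
        d_alpha0 += float(np.sum(g_u1))
        d_alpha = d_alpha + W1.T @ g_u1
        g_z = lam_t * rho / root - z
        d_beta0 = float(np.sum(g_z * (-1.0 / sigma)))
        d_beta = X1.T @ (g_z * (-1.0 / sigma))
        d_sigma = float(np.sum(g_z * (-z / sigma) - 1.0 / sigma))
        d_rho = float(np.sum(lam_t * (z + rho * u[sel]) / onem**1.5))
    return {
        "alpha0": d_alpha0, "alpha": np.asarray(d_alpha), "beta0": d_beta0,
        "beta": np.asarray(d_beta), "sigma": d_sigma, "rho": d_rho,
    }


def latent_conditional(
    params: ModelParams,
    data: SelectionData,
    i: int,
    which: LatentConditional,
    *,
    y: float | None = None,
    s_star: float | None = None,
) -> GaussianSpec:
    """Gaussian conditional laws of the latent pair (s*_i, y*_i).

    Under the (rho_tilde, sigma_tilde_sq) reparametrization,

        s*_i               ~ N(alpha0 + w'alpha, 1)
        s*_i | y*_i        ~ N(alpha0 + w'alpha
                               + rho_tilde (y_i - beta0 - x'beta)
                                 / (sigma_tilde^2 + rho_tilde^2),
                               sigma_tilde^2 / (sigma_tilde^2 + rho_tilde^2))
        y*_i | s*_i        ~ N(beta0 + x'beta
                               + rho_tilde (s*_i - alpha0 - w'alpha),
                               sigma_tilde^2)

    The truncation interval attached to the s* laws follows the observed
    indicator: (0, inf) when selected, (-inf, 0) otherwise; the y* law is
    untruncated.
    """
    which = LatentConditional(which)
    w = data.selection_covariates[i]
    x = data.outcome_covariates[i]
    mu_s = params.alpha0 + w @ params.alpha
    mu_y = params.beta0 + x @ params.beta
    trunc = Truncation.POSITIVE if data.selected[i] == 1 else Truncation.NEGATIVE

    if which is LatentConditional.S_STAR_MARGINAL:
        return GaussianSpec(float(mu_s), 1.0, trunc)
    if which is LatentConditional.S_STAR_GIVEN_Y:
        if data.selected[i] != 1:
            raise ValueError("s_star_given_y requires a selected unit (outcome observed)")
        yi = data.outcome[i] if y is None else y
        total = params.sigma_tilde_sq + params.rho_tilde**2
        mean = mu_s + params.rho_tilde * (yi - mu_y) / total
        return GaussianSpec(float(mean), params.sigma_tilde_sq / total, trunc)
    # y* | s*
    if s_star is None:
        raise ValueError("y_star_given_s_star requires the conditioning s_star value")
    mean = mu_y + params.rho_tilde * (s_star - mu_s)
    return GaussianSpec(float(mean), params.sigma_tilde_sq, Truncation.NONE)
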