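"""Frequentist reference methods: probit, Heckman two-step, full MLE,
and forward stepwise selection by BIC.

These are the classical estimators the Bayesian sampler is compared against.
They also supply starting values and the 5%-significance inclusion mask used
to initialize the Gibbs chain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .data import SelectionData
from .model_core import ModelParams, inverse_mills, kappa, log_likelihood, score

logger = logging.getLogger(__name__)

__all__ = [
    "ModelId",
    "FitResult",
    "ProbitResult",
    "probit_fit",
    "heckman_two_step",
    "mle_fit",
    "forward_stepwise",
]


@dataclass(frozen=True)
class ModelId:
    """Inclusion masks identifying one (outcome, selection) model."""

    outcome: tuple
    selection: tuple

    def __post_init__(self):
        object.__setattr__(self, "outcome", tuple(int(g) for g in self.outcome))
        object.__setattr__(self, "selection", tuple(int(g) for g in self.selection))
        if not set(self.outcome) <= {0, 1} or not set(self.selection) <= {0, 1}:
            raise ValueError("masks must be binary")

    @property
    def outcome_mask(self) -> np.ndarray:
        return np.array(self.outcome, dtype=bool)

    @property
    def selection_mask(self) -> np.ndarray:
        return np.array(self.selection, dtype=bool)

    @property
    def size_outcome(self) -> int:
        return sum(self.outcome)

    @property
    def size_selection(self) -> int:
        return sum(self.selection)

    @classmethod
    def full(cls, p: int, q: int) -> "ModelId":
        return cls((1,) * p, (1,) * q)

    @classmethod
    def null(cls, p: int, q: int) -> "ModelId":
        return cls((0,) * p, (0,) * q)


@dataclass
class ProbitResult:
    intercept: float
    coefs: np.ndarray
    cov: np.ndarray | None
    converged: bool


@dataclass
class FitResult:
    """Estimates from a frequentist fit of the sample selection model.

    ``bse_*`` are Wald standard errors (present only when converged with a
    positive-definite observed information); ``delta`` is the two-step IMR
    coefficient, which estimates sigma * rho.
    """

    params: ModelParams
    model: ModelId
    converged: bool
    llf: float = np.nan
    n_iter: int = 0
    bse_alpha0: float | None = None
    bse_alpha: np.ndarray | None = None
    bse_beta0: float | None = None
    bse_beta: np.ndarray | None = None
    delta: float | None = None
    delta_se: float | None = None
    collinearity_warning: bool = False

    @property
    def bse(self):
        if self.bse_alpha is None:
            return None
        return np.concatenate(
            [[self.bse_alpha0], self.bse_alpha, [self.bse_beta0], self.bse_beta]
        )

    def bic(self, n: int) -> float:
        """BIC = -2 llf + k log n with k = 4 + number of active coefficients
        (two intercepts, sigma_tilde^2, rho_tilde, plus active slopes)."""
        k = 4 + self.model.size_outcome + self.model.size_selection
        return -2.0 * self.llf + k * np.log(n)


def probit_fit(selection_covariates, selected) -> ProbitResult:
    """ML probit of the selection indicator on (1, W).

    Perfect separation and other failures are reported through the
    ``converged`` flag, never raised.
    """
    selected = np.asarray(selected)
    if selected.min() == selected.max():
        raise ValueError("selected must contain both 0s and 1s")
    cov = np.asarray(selection_covariates, dtype=float)
    cov = cov.reshape(selected.shape[0], -1)
    W = np.column_stack([np.ones(selected.shape[0]), cov])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Probit(selected, W).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        cov = np.asarray(res.cov_params())
        if not np.isfinite(cov).all() or not np.isfinite(res.params).all():
            converged = False
        # a huge fitted scale is the practical signature of separation
        if np.abs(res.params).max() > 1e3 or (converged and np.abs(np.diag(cov)).max() > 1e6):
            converged = False
        return ProbitResult(float(res.params[0]), np.asarray(res.params[1:]), cov, converged)
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        q = W.shape[1] - 1
        return ProbitResult(0.0, np.zeros(q), None, False)


def heckman_two_step(data: SelectionData) -> FitResult:
    """Heckman's two-step estimator.

    Probit of s on (1, W) over the full sample gives fitted indices
    u_i = alpha0 + w_i'alpha; the inverse Mills ratio lambda(u_i) then enters
    an OLS of y on (1, x, lambda) over selected units.  The IMR coefficient
    delta estimates sigma * rho and is reported as such; no (sigma, rho)
    back-out is attempted.  A near-constant or collinear IMR column raises a
    condition-number flag.
    """
    p_dim = data.n_outcome_covariates
    if data.n_selected < p_dim + 3:
        raise ValueError("two-step requires at least p + 3 selected units")
    probit = probit_fit(data.selection_covariates, data.selected)
    u = probit.intercept + data.selection_covariates @ probit.coefs
    sel = data.observed_mask
    lam = inverse_mills(u[sel])
    design = np.column_stack(
        [np.ones(int(sel.sum())), data.outcome_covariates[sel], lam]
    )
    # VIF of the IMR column: fraction of its variance not explained by
    # (1, x).  Near-linear IMR over a narrow index range (the classic
    # no-exclusion-restriction pathology) drives this towards zero.
    base = design[:, :-1]
    coef, *_ = np.linalg.lstsq(base, lam, rcond=None)
    resid_frac = float(np.var(lam - base @ coef) / max(np.var(lam), 1e-300))
    collinear = lam.std() < 1e-10 or resid_frac < 1e-2
    if collinear:
        logger.warning(
            "IMR column is nearly collinear with the outcome design "
            "(only %.2e of its variance is unexplained by the covariates); "
            "two-step estimates are unstable",
            resid_frac,
        )
    ols = sm.OLS(data.outcome[sel], design).fit()
    delta = float(ols.params[-1])
    resid = ols.resid
    # residual-moment estimate of sigma^2 (used only for starting values)
    sigma_sq_hat = float(resid @ resid) / resid.shape[0] + delta**2 * float(
        np.mean(kappa(u[sel]))
    )
    sigma_tilde_sq = max(sigma_sq_hat - delta**2, 1e-4)
    params = ModelParams(
        alpha0=probit.intercept, alpha=probit.coefs,
        beta0=float(ols.params[0]), beta=np.asarray(ols.params[1:-1]),
        rho_tilde=delta, sigma_tilde_sq=sigma_tilde_sq,
    )
    fit = FitResult(
        params=params,
        model=ModelId.full(p_dim, data.n_selection_covariates),
        converged=probit.converged,
        llf=log_likelihood(_clip_rho(params), data),
        delta=float(delta),
        delta_se=float(ols.bse[-1]),
        collinearity_warning=collinear,
    )
    fit.bse_beta0 = float(ols.bse[0])
    fit.bse_beta = np.asarray(ols.bse[1:-1])
    if probit.cov is not None:
        se = np.sqrt(np.diag(probit.cov))
        fit.bse_alpha0, fit.bse_alpha = float(se[0]), se[1:]
    return fit


def _clip_rho(params: ModelParams, max_abs_rho: float = 0.995) -> ModelParams:
    """Pull |rho| inside the open interval so the likelihood is evaluable."""
    if abs(params.rho) < max_abs_rho:
        return params
    sigma = params.sigma
    rho = math_copysign(max_abs_rho, params.rho_tilde)
    return ModelParams.from_natural(
        params.alpha0, params.alpha, params.beta0, params.beta, sigma, rho
    )


def math_copysign(x, y):
    return abs(x) if y >= 0 else -abs(x)


def _pack(params: ModelParams, model: ModelId) -> np.ndarray:
    return np.concatenate(
        [
            [params.alpha0], params.alpha[model.selection_mask],
            [params.beta0], params.beta[model.outcome_mask],
            [params.rho_tilde], [np.log(params.sigma_tilde_sq)],
        ]
    )


def _unpack(theta: np.ndarray, model: ModelId, p: int, q: int) -> ModelParams:
    qa = model.size_selection
    pa = model.size_outcome
    alpha = np.zeros(q)
    alpha[model.selection_mask] = theta[1 : 1 + qa]
    beta = np.zeros(p)
    beta[model.outcome_mask] = theta[2 + qa : 2 + qa + pa]
    return ModelParams(
        alpha0=float(theta[0]), alpha=alpha,
        beta0=float(theta[1 + qa]), beta=beta,
        rho_tilde=float(theta[-2]), sigma_tilde_sq=float(np.exp(theta[-1])),
    )


def _neg_ll_and_grad(theta, data, model, p, q):
    # a wandering line search can propose arbitrarily extreme scales; reject
    # them with a large finite value so BFGS backtracks
    if not np.all(np.isfinite(theta)) or abs(theta[-1]) > 80 or np.abs(theta).max() > 1e6:
        return 1e12, np.zeros_like(theta)
    params = _unpack(theta, model, p, q)
    ll = log_likelihood(params, data)
    if not np.isfinite(ll):
        return 1e12, np.zeros_like(theta)
    g = score(params, data)
    sigma = params.sigma
    rho = params.rho
    sts = params.sigma_tilde_sq
    rt = params.rho_tilde
    g_sigma, g_rho = g["sigma"], g["rho"]
    # chain rule into (rho_tilde, log sigma_tilde_sq)
    d_rt = g_sigma * rt / sigma + g_rho * sts / sigma**3
    d_log_sts = (g_sigma / (2.0 * sigma) - g_rho * rt / (2.0 * sigma**3)) * sts
    grad = np.concatenate(
        [
            [g["alpha0"]], g["alpha"][model.selection_mask],
            [g["beta0"]], g["beta"][model.outcome_mask],
            [d_rt], [d_log_sts],
        ]
    )
    return -ll, -grad


def mle_fit(
    data: SelectionData,
    model: ModelId | None = None,
    start: ModelParams | None = None,
    *,
    compute_se: bool = True,
) -> FitResult:
    """Maximize the sample-selection log-likelihood over a masked model.

    Works in the unconstrained parametrization (rho_tilde, log sigma_tilde^2)
    so sigma_tilde^2 > 0 and |rho| < 1 hold by construction, with the
    analytic score.  Starting values default to the two-step estimates; a
    null start is tried as a second attempt.  Non-convergence is reported
    through the flag (honest: optimizer success, small gradient, and - when
    standard errors are requested - a positive-definite observed
    information), never raised.
    """
    p, q = data.n_outcome_covariates, data.n_selection_covariates
    if model is None:
        model = ModelId.full(p, q)

    starts: list[ModelParams] = []
    if start is not None:
        starts.append(start)
    else:
        try:
            ts = heckman_two_step(data)
            if np.isfinite(ts.params.rho_tilde) and ts.params.sigma_tilde_sq > 0:
                starts.append(_clip_rho(ts.params))
        except (ValueError, np.linalg.LinAlgError):
            pass
    null = ModelParams(0.0, np.zeros(q), 0.0, np.zeros(p), 0.0, 1.0)
    if data.n_selected:
        y1 = data.outcome[data.observed_mask]
        null.beta0 = float(y1.mean())
        null.sigma_tilde_sq = float(max(y1.var(), 1e-2))
    starts.append(null)

    best = None
    for s in starts:
        theta0 = _pack(s, model)
        with np.errstate(all="ignore"):
            res = optimize.minimize(
                _neg_ll_and_grad, theta0, args=(data, model, p, q),
                jac=True, method="BFGS",
                options={"maxiter": 500, "gtol": 1e-6},
            )
        grad_ok = np.max(np.abs(res.jac)) < 1e-4 * (1.0 + abs(res.fun))
        ok = bool(res.success or grad_ok) and np.isfinite(res.fun)
        if best is None or res.fun < best[0].fun:
            best = (res, ok)
        if ok:
            best = (res, ok)
            break
    res, ok = best
    params = _unpack(res.x, model, p, q)
    fit = FitResult(
        params=params, model=model, converged=ok,
        llf=-float(res.fun), n_iter=int(res.nit),
    )
    if ok and compute_se:
        with np.errstate(all="ignore"):
            hess = approx_hess1(
                res.x, lambda t: _neg_ll_and_grad(t, data, model, p, q)[0]
            )
        try:
            eigvals = np.linalg.eigvalsh(hess)
            if eigvals.min() <= 0:
                fit.converged = False
            else:
                cov = np.linalg.inv(hess)
                se = np.sqrt(np.diag(cov))
                qa = model.size_selection
                fit.bse_alpha0 = float(se[0])
                bse_alpha = np.full(q, np.nan)
                bse_alpha[model.selection_mask] = se[1 : 1 + qa]
                fit.bse_alpha = bse_alpha
                fit.bse_beta0 = float(se[1 + qa])
                bse_beta = np.full(p, np.nan)
                bse_beta[model.outcome_mask] = se[2 + qa : -2]
                fit.bse_beta = bse_beta
        except np.linalg.LinAlgError:
            fit.converged = False
    return fit


def forward_stepwise(data: SelectionData, max_steps: int | None = None):
    """Forward selection by BIC over both equations.

    Starts from the null model (intercepts, sigma_tilde^2, rho_tilde only);
    each round fits every single-variable addition to either equation by
    maximum likelihood and accepts the BIC-minimizing one; stops when no
    addition lowers the BIC.  BIC uses the total sample size.  Candidate
    fits that fail to converge are skipped with a logged warning.  Exact BIC
    ties break deterministically: selection equation before outcome, then
    lowest column index.

    Returns ``(model_id, trace)`` where the trace lists the accepted
    ``(ModelId, FitResult, bic)`` path, null model first.
    """
    p, q = data.n_outcome_covariates, data.n_selection_covariates
    n = data.n
    current = ModelId.null(p, q)
    fit = mle_fit(data, current, compute_se=False)
    trace = [(current, fit, fit.bic(n))]
    max_steps = max_steps if max_steps is not None else p + q
    for _ in range(max_steps):
        best_bic = trace[-1][2]
        best = None
        # selection equation first, then outcome; strict < keeps the
        # first-visited candidate on exact ties
        candidates = [("sel", k) for k in range(q) if not current.selection[k]]
        candidates += [("out", j) for j in range(p) if not current.outcome[j]]
        for eq, idx in candidates:
            out = list(current.outcome)
            sel = list(current.selection)
            (sel if eq == "sel" else out)[idx] = 1
            cand = ModelId(tuple(out), tuple(sel))
            cand_fit = mle_fit(
                data, cand, start=trace[-1][1].params, compute_se=False
            )
            if not cand_fit.converged:
                logger.warning("stepwise: candidate %s failed to converge; skipped", cand)
                continue
            bic = cand_fit.bic(n)
            if bic < best_bic:
                best_bic, best = bic, (cand, cand_fit)
        if best is None:
            break
        current = best[0]
        trace.append((current, best[1], best_bic))
    return current, trace
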