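"""Spike-and-slab prior families and their default elicitation.

Each regression coefficient carries a two-component continuous mixture prior
indexed by a binary inclusion indicator gamma:

    coef | gamma, v  ~  (1-gamma) N(0, tau0^2 v)  +  gamma N(0, tau1^2 v)

where v is a positive mixing scale whose distribution (degenerate at 1,
exponential, or inverse-gamma) turns each component into a normal, Laplace,
or Student-t marginal.  Class I priors use these variances directly; Class II
additionally scales the outcome-equation coefficient variances by the
conditional outcome variance sigma_tilde^2, so effect sizes are judged
relative to the unexplained noise.

Indicators are iid Bernoulli(r) with r ~ Beta(a0, b0), i.e. a Beta-Binomial
prior on model size, which penalizes multiplicity automatically.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from scipy.special import betaln

__all__ = [
    "MixtureKind",
    "MixtureFamily",
    "PriorClass",
    "SpikeSlabSpec",
    "default_spec",
    "inclusion_probability",
    "model_size_log_prior",
    "marginal_coef_logdensity",
    "induced_rho_prior_sample",
]


class MixtureKind(str, enum.Enum):
    NORMAL = "normal"
    LAPLACE = "laplace"
    STUDENT_T = "student_t"


class PriorClass(str, enum.Enum):
    I = "I"
    II = "II"


@dataclass(frozen=True)
class MixtureFamily:
    """Scale-mixing family of a spike, slab, or intercept component.

    normal    -> mixing variable is the constant 1
    laplace   -> v ~ Exp(rate 1/2) (mean 2), giving a Laplace(scale tau)
                 marginal
    student_t -> v ~ InvGamma(dof/2, dof/2), giving a Student-t(dof) marginal
                 with scale tau
    """

    kind: MixtureKind = MixtureKind.NORMAL
    dof: float = 3.0

    def __post_init__(self):
        object.__setattr__(self, "kind", MixtureKind(self.kind))
        if self.kind is MixtureKind.STUDENT_T and not self.dof > 0:
            raise ValueError("student_t mixing requires dof > 0")

    def mixing_logpdf(self, v):
        """Log density of the mixing scale v (0 for the degenerate normal)."""
        v = np.asarray(v, dtype=float)
        if self.kind is MixtureKind.NORMAL:
            return np.zeros_like(v)
        if self.kind is MixtureKind.LAPLACE:
            return stats.expon.logpdf(v, scale=2.0)
        return stats.invgamma.logpdf(v, self.dof / 2.0, scale=self.dof / 2.0)

    def mixing_rvs(self, size, rng: np.random.Generator):
        if self.kind is MixtureKind.NORMAL:
            return np.ones(size)
        if self.kind is MixtureKind.LAPLACE:
            return rng.exponential(2.0, size)
        return (self.dof / 2.0) / rng.gamma(self.dof / 2.0, 1.0, size)

    def mixing_mean(self) -> float:
        """Prior mean of v (used for null initialization); 1 when undefined."""
        if self.kind is MixtureKind.NORMAL:
            return 1.0
        if self.kind is MixtureKind.LAPLACE:
            return 2.0
        return self.dof / (self.dof - 2.0) if self.dof > 2 else 1.0


@dataclass
class SpikeSlabSpec:
    """Full prior configuration for both equations.

    Scale parameters are standard deviations (tau), not variances.  The
    remaining blocks: r ~ Beta(a0, b0); rho_tilde | sigma_tilde ~
    N(0, tau_rho sigma_tilde^2); sigma_tilde^2 ~ InvGamma(c, d); intercepts
    beta0 ~ N(0, eta_outcome v0) and alpha0 ~ N(0, eta_selection v0) with
    their own mixing scales.
    """

    prior_class: PriorClass = PriorClass.I
    tau0_beta: float = 0.02
    tau1_beta: float = 0.5
    tau0_alpha: float = 0.02
    tau1_alpha: float = math.sqrt(3.0) / math.pi
    spike_family_outcome: MixtureFamily = field(default_factory=MixtureFamily)
    slab_family_outcome: MixtureFamily = field(default_factory=MixtureFamily)
    spike_family_selection: MixtureFamily = field(default_factory=MixtureFamily)
    slab_family_selection: MixtureFamily = field(default_factory=MixtureFamily)
    intercept_family_outcome: MixtureFamily = field(default_factory=MixtureFamily)
    intercept_family_selection: MixtureFamily = field(default_factory=MixtureFamily)
    a0: float = 1.0
    b0: float = 1.0
    tau_rho: float = 5.0
    c: float = 1.0
    d: float = 1.0
    eta_outcome: float = 100.0
    eta_selection: float = 100.0
    # Class II only: whether the outcome intercept variance is also scaled by
    # sigma_tilde^2 (off by default; the coefficient priors always are).
    scale_outcome_intercept: bool = False

    def __post_init__(self):
        self.prior_class = PriorClass(self.prior_class)
        for name in ("tau0_beta", "tau1_beta", "tau0_alpha", "tau1_alpha",
                     "a0", "b0", "tau_rho", "c", "d",
                     "eta_outcome", "eta_selection"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.tau0_beta < self.tau1_beta:
            raise ValueError("need tau0_beta < tau1_beta")
        if not self.tau0_alpha < self.tau1_alpha:
            raise ValueError("need tau0_alpha < tau1_alpha")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["prior_class"] = self.prior_class.value
        for key, val in d.items():
            if isinstance(val, dict) and "kind" in val:
                val["kind"] = MixtureFamily(**val).kind.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpikeSlabSpec":
        d = dict(d)
        for key in list(d):
            if key.endswith(("_outcome", "_selection")) and isinstance(d[key], dict):
                d[key] = MixtureFamily(**d[key])
        return cls(**d)


def default_spec(
    n: int,
    p: int,
    q: int,
    *,
    betabinom: str = "uniform",
    prior_class: PriorClass | str = PriorClass.I,
    family: MixtureFamily | MixtureKind | str = MixtureKind.NORMAL,
    slab_multiplier: float = 1.0,
    spike_multiplier: float = 1.0,
    **overrides,
) -> SpikeSlabSpec:
    """Default prior elicitation as a function of the problem dimensions.

    tau0_beta = (n p)^{-1/2}, tau0_alpha = (n q)^{-1/2} (spikes shrink with
    both sample size and dimension); tau1_alpha = sqrt(3)/pi matches the
    probit scale; tau1_beta = (4 log 500)^{-1/2} sqrt(log n), equal to 0.5 at
    n = 500 and growing with log n.  Beta-Binomial hyperparameters are (1, 1)
    ("uniform", flat over model size) or (1, p + q) ("sparse", monotone
    decreasing).  tau_rho = 5, c = d = 1, eta = 100.

    Laplace components have their tau divided by sqrt(2) so the marginal
    prior variance matches the normal family at the same tau.  The
    ``slab_multiplier``/``spike_multiplier`` scalars rescale the slab/spike
    standard deviations for sensitivity analysis.
    """
    if min(n, p, q) < 1:
        raise ValueError("need n, p, q >= 1")
    if betabinom == "uniform":
        a0, b0 = 1.0, 1.0
    elif betabinom == "sparse":
        a0, b0 = 1.0, float(p + q)
    else:
        raise ValueError("betabinom must be 'uniform' or 'sparse'")

    if isinstance(family, MixtureFamily):
        fam = family
    else:
        fam = MixtureFamily(kind=MixtureKind(family))
    rescale = 1.0 / math.sqrt(2.0) if fam.kind is MixtureKind.LAPLACE else 1.0

    tau0_beta = (n * p) ** -0.5 * spike_multiplier * rescale
    tau0_alpha = (n * q) ** -0.5 * spike_multiplier * rescale
    tau1_beta = (4.0 * math.log(500.0)) ** -0.5 * math.sqrt(math.log(n))
    tau1_beta *= slab_multiplier * rescale
    tau1_alpha = math.sqrt(3.0) / math.pi * slab_multiplier * rescale

    kwargs = dict(
        prior_class=PriorClass(prior_class),
        tau0_beta=tau0_beta, tau1_beta=tau1_beta,
        tau0_alpha=tau0_alpha, tau1_alpha=tau1_alpha,
        spike_family_outcome=fam, slab_family_outcome=fam,
        spike_family_selection=fam, slab_family_selection=fam,
        intercept_family_outcome=fam, intercept_family_selection=fam,
        a0=a0, b0=b0,
    )
    kwargs.update(overrides)
    return SpikeSlabSpec(**kwargs)


def _norm_logpdf(x, sd):
    return -0.5 * (x / sd) ** 2 - math.log(sd) - 0.5 * math.log(2.0 * math.pi)


def inclusion_probability(coef, v, tau0, tau1, r, sigma_tilde=1.0):
    """Bernoulli inclusion weight of a coefficient given its mixing scale.

    Returns r N(coef; 0, tau1^2 v s^2) / [r N(coef; 0, tau1^2 v s^2)
    + (1-r) N(coef; 0, tau0^2 v s^2)] with fully normalized Gaussian
    densities (s = sigma_tilde, used by Class II outcome coefficients).
    Computed in log space.
    """
    if min(tau0, tau1) <= 0 or v <= 0 or sigma_tilde <= 0:
        raise ValueError("scales must be strictly positive")
    if not 0.0 < r < 1.0:
        raise ValueError("r must lie in (0, 1)")
    root_v = math.sqrt(v) * sigma_tilde
    log_slab = math.log(r) + _norm_logpdf(coef, tau1 * root_v)
    log_spike = math.log(1.0 - r) + _norm_logpdf(coef, tau0 * root_v)
    return float(np.exp(log_slab - np.logaddexp(log_slab, log_spike)))


def model_size_log_prior(k: int, m: int, a0: float, b0: float) -> float:
    """Log Beta-Binomial prior probability of one specific configuration.

    For a model including k of m candidate variables,
    log B(a0 + k, b0 + m - k) - log B(a0, b0); summing exp over all 2^m
    configurations gives 1.
    """
    if not 0 <= k <= m:
        raise ValueError("need 0 <= k <= m")
    return float(betaln(a0 + k, b0 + m - k) - betaln(a0, b0))


def marginal_coef_logdensity(coef, family: MixtureFamily, tau: float):
    """Log marginal prior density of a coefficient, mixing scale integrated out.

    normal -> N(0, tau^2); laplace -> Laplace(scale tau); student_t ->
    tau-scaled Student-t with ``family.dof`` degrees of freedom.
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    coef = np.asarray(coef, dtype=float)
    if family.kind is MixtureKind.NORMAL:
        out = stats.norm.logpdf(coef, scale=tau)
    elif family.kind is MixtureKind.LAPLACE:
        out = stats.laplace.logpdf(coef, scale=tau)
    else:
        out = stats.t.logpdf(coef, df=family.dof, scale=tau)
    return out if out.ndim else float(out)


def induced_rho_prior_sample(spec: SpikeSlabSpec, count: int, rng: np.random.Generator):
    """Draws from the prior induced on the error correlation rho.

    Samples sigma_tilde^2 ~ InvGamma(c, d) and rho_tilde | sigma_tilde ~
    N(0, tau_rho sigma_tilde^2), then maps to rho = rho_tilde /
    sqrt(sigma_tilde^2 + rho_tilde^2) in (-1, 1).  For tau_rho around 5 the
    induced density is U-shaped, similar to a Beta(1/2, 1/2) rescaled to
    (-1, 1).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    sigma_tilde_sq = spec.d / rng.gamma(spec.c, 1.0, count)
    rho_tilde = rng.normal(0.0, np.sqrt(spec.tau_rho * sigma_tilde_sq))
    return rho_tilde / np.sqrt(sigma_tilde_sq + rho_tilde**2)
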