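"""Full-conditional correctness of every Gibbs step.

Master oracle: for each updated block, the log density difference of the
step's sampling law between two candidate values must equal the difference
of the unnormalized complete-data joint log posterior evaluated at the two
corresponding states, to 1e-8.  This pins each conditional to the joint
without re-deriving any algebra from the sampler's own code path.
"""

import copy
import math

import numpy as np
import pytest
from scipy import stats

from heckselect import MixtureFamily, MixtureKind
from heckselect.gibbs import (
    indicator_weights,
    log_joint,
    outcome_block,
    selection_block,
    sigma_conditional,
    step_latent,
    step_scales,
)
from conftest import random_state

RTOL = 1e-8


def _specs(spec_factory):
    out = []
    for prior_class in ("I", "II"):
        for family in ("normal", "laplace", "student_t"):
            out.append(
                spec_factory(n=200, p=2, q=2, prior_class=prior_class, family=family)
            )
    # mixed families: heavy-tailed slab over a normal spike
    mixed = spec_factory(n=200, p=2, q=2)
    mixed.slab_family_outcome = MixtureFamily(MixtureKind.LAPLACE)
    mixed.slab_family_selection = MixtureFamily(MixtureKind.STUDENT_T, dof=4)
    out.append(mixed)
    return out


def _joint_with(state, data, spec, **replacements):
    s = copy.deepcopy(state)
    for name, value in replacements.items():
        if hasattr(s.params, name):
            setattr(s.params, name, value)
        else:
            setattr(s, name, value)
    return log_joint(s, data, spec)


def _gaussian_logpdf_from_canonical(theta, precision, rhs):
    mean = np.linalg.solve(precision, rhs)
    diff = theta - mean
    return -0.5 * diff @ precision @ diff  # constant dropped; ratios only


@pytest.fixture(params=range(7))
def case(request, tiny_data, spec_factory):
    data, _ = tiny_data
    spec = _specs(spec_factory)[request.param]
    state = random_state(data, spec, seed=100 + request.param)
    return data, spec, state


class TestBlockConditionals:
    def test_selection_block_matches_joint_ratio(self, case, rng):
        data, spec, state = case
        precision, rhs = selection_block(state, data, spec)
        for _ in range(4):
            t1 = rng.normal(scale=0.7, size=3)
            t2 = rng.normal(scale=0.7, size=3)
            lhs = _gaussian_logpdf_from_canonical(
                t1, precision, rhs
            ) - _gaussian_logpdf_from_canonical(t2, precision, rhs)
            rhs_ratio = _joint_with(
                state, data, spec, alpha0=float(t1[0]), alpha=t1[1:]
            ) - _joint_with(state, data, spec, alpha0=float(t2[0]), alpha=t2[1:])
            assert lhs == pytest.approx(rhs_ratio, rel=RTOL, abs=1e-8)

    def test_outcome_block_matches_joint_ratio(self, case, rng):
        data, spec, state = case
        precision, rhs = outcome_block(state, data, spec)
        for _ in range(4):
            t1 = rng.normal(scale=0.7, size=4)
            t2 = rng.normal(scale=0.7, size=4)
            lhs = _gaussian_logpdf_from_canonical(
                t1, precision, rhs
            ) - _gaussian_logpdf_from_canonical(t2, precision, rhs)
            joint1 = _joint_with(
                state, data, spec,
                beta0=float(t1[0]), beta=t1[1:3], rho_tilde=float(t1[3]),
            )
            joint2 = _joint_with(
                state, data, spec,
                beta0=float(t2[0]), beta=t2[1:3], rho_tilde=float(t2[3]),
            )
            assert lhs == pytest.approx(joint1 - joint2, rel=RTOL, abs=1e-8)

    def test_sigma_conditional_matches_joint_ratio(self, case):
        data, spec, state = case
        shape, rate = sigma_conditional(state, data, spec)
        for v1, v2 in [(0.6, 1.4), (0.9, 2.3)]:
            lhs = stats.invgamma.logpdf(v1, shape, scale=rate) - stats.invgamma.logpdf(
                v2, shape, scale=rate
            )
            rhs_ratio = _joint_with(state, data, spec, sigma_tilde_sq=v1) - _joint_with(
                state, data, spec, sigma_tilde_sq=v2
            )
            assert lhs == pytest.approx(rhs_ratio, rel=RTOL, abs=1e-8)

    def test_empty_sum_sigma_shape(self, tiny_data, spec_factory):
        # no selected units: c* = c + 1/2, d* = d (rho_tilde set to 0)
        data, _ = tiny_data
        from heckselect import SelectionData

        censored = SelectionData(
            np.full(data.n, np.nan), np.zeros(data.n, dtype=int),
            data.outcome_covariates, data.selection_covariates,
        )
        spec = spec_factory(p=2, q=2)
        state = random_state(censored, spec, seed=3)
        state.params.rho_tilde = 0.0
        shape, rate = sigma_conditional(state, censored, spec)
        assert shape == pytest.approx(spec.c + 0.5)
        assert rate == pytest.approx(spec.d)

    def test_class_membership_irrelevant_without_outcome_terms(
        self, tiny_data, spec_factory
    ):
        # Class I and II sigma conditionals agree when beta is empty in effect
        data, _ = tiny_data
        s1 = spec_factory(prior_class="I")
        s2 = spec_factory(prior_class="II")
        state = random_state(data, s1, seed=5)
        state.params.beta = np.zeros(2)
        a1 = sigma_conditional(state, data, s1)
        a2 = sigma_conditional(state, data, s2)
        assert a1[0] + 1.0 == pytest.approx(a2[0])  # p/2 shape shift only
        assert a1[1] == pytest.approx(a2[1])


class TestIndicatorConditionals:
    """Coefficients are pinned to moderate values so neither mixture
    component underflows; saturated weights (0/1) carry no ratio signal."""

    def test_weights_match_joint_ratio(self, case):
        data, spec, state = case
        state = copy.deepcopy(state)
        state.params.beta = np.array([0.035, -0.02])
        s_out = (
            math.sqrt(state.params.sigma_tilde_sq)
            if spec.prior_class.value == "II" else 1.0
        )
        w = indicator_weights(
            state.params.beta, state.v_out, spec.tau0_beta, spec.tau1_beta,
            state.r, spec.spike_family_outcome, spec.slab_family_outcome, s_out,
        )
        for j in range(2):
            g1, g0 = state.gamma_out.copy(), state.gamma_out.copy()
            g1[j], g0[j] = 1, 0
            ratio = _joint_with(state, data, spec, gamma_out=g1) - _joint_with(
                state, data, spec, gamma_out=g0
            )
            lhs = math.log(w[j]) - math.log1p(-w[j])
            assert lhs == pytest.approx(ratio, rel=RTOL, abs=1e-8)

    def test_selection_weights_match_joint_ratio(self, case):
        data, spec, state = case
        state = copy.deepcopy(state)
        state.params.alpha = np.array([-0.03, 0.015])
        w = indicator_weights(
            state.params.alpha, state.v_sel, spec.tau0_alpha, spec.tau1_alpha,
            state.r, spec.spike_family_selection, spec.slab_family_selection,
        )
        for k in range(2):
            g1, g0 = state.gamma_sel.copy(), state.gamma_sel.copy()
            g1[k], g0[k] = 1, 0
            ratio = _joint_with(state, data, spec, gamma_sel=g1) - _joint_with(
                state, data, spec, gamma_sel=g0
            )
            lhs = math.log(w[k]) - math.log1p(-w[k])
            assert lhs == pytest.approx(ratio, rel=RTOL, abs=1e-8)

    def test_r_conditional_matches_joint_ratio(self, case):
        data, spec, state = case
        k = int(state.gamma_out.sum() + state.gamma_sel.sum())
        m = state.gamma_out.size + state.gamma_sel.size
        a1, b1 = spec.a0 + k, spec.b0 + m - k
        for r1, r2 in [(0.2, 0.7), (0.45, 0.9)]:
            lhs = stats.beta.logpdf(r1, a1, b1) - stats.beta.logpdf(r2, a1, b1)
            ratio = _joint_with(state, data, spec, r=r1) - _joint_with(
                state, data, spec, r=r2
            )
            assert lhs == pytest.approx(ratio, rel=RTOL, abs=1e-8)


class TestLatentConditionalStep:
    def test_truncation_contract(self, case, rng):
        data, spec, state = case
        step_latent(state, data, rng)
        assert (state.s_star[data.observed_mask] > 0).all()
        assert (state.s_star[~data.observed_mask] <= 0).all()

    def test_selected_unit_density_matches_joint_ratio(self, case):
        data, spec, state = case
        p = state.params
        i = int(np.flatnonzero(data.observed_mask)[0])
        u = p.alpha0 + data.selection_covariates[i] @ p.alpha
        total = p.rho_tilde**2 + p.sigma_tilde_sq
        mean = u + p.rho_tilde / total * (
            data.outcome[i] - p.beta0 - data.outcome_covariates[i] @ p.beta
        )
        sd = math.sqrt(p.sigma_tilde_sq / total)
        for s1, s2 in [(0.3, 1.7), (0.05, 0.9)]:
            lhs = stats.norm.logpdf(s1, mean, sd) - stats.norm.logpdf(s2, mean, sd)
            ss1, ss2 = state.s_star.copy(), state.s_star.copy()
            ss1[i], ss2[i] = s1, s2
            ratio = _joint_with(state, data, spec, s_star=ss1) - _joint_with(
                state, data, spec, s_star=ss2
            )
            assert lhs == pytest.approx(ratio, rel=RTOL, abs=1e-8)

    def test_censored_unit_density_matches_joint_ratio(self, case):
        data, spec, state = case
        p = state.params
        i = int(np.flatnonzero(~data.observed_mask)[0])
        u = p.alpha0 + data.selection_covariates[i] @ p.alpha
        for s1, s2 in [(-0.2, -1.5), (-0.01, -3.0)]:
            lhs = stats.norm.logpdf(s1, u, 1.0) - stats.norm.logpdf(s2, u, 1.0)
            ss1, ss2 = state.s_star.copy(), state.s_star.copy()
            ss1[i], ss2[i] = s1, s2
            ratio = _joint_with(state, data, spec, s_star=ss1) - _joint_with(
                state, data, spec, s_star=ss2
            )
            assert lhs == pytest.approx(ratio, rel=RTOL, abs=1e-8)

    def test_extreme_mean_still_finite(self, tiny_data, spec_factory, rng):
        data, _ = tiny_data
        spec = spec_factory()
        state = random_state(data, spec, seed=9)
        state.params.alpha0 = -10.0
        state.params.alpha = np.zeros(2)
        state.params.rho_tilde = 0.0
        step_latent(state, data, rng)
        assert np.isfinite(state.s_star).all()
        assert (state.s_star[data.observed_mask] > 0).all()

    def test_far_tail_matches_rejection_oracle(self, rng):
        # N(-10, 1) truncated to (0, inf): the standardized bound is 10.
        # Oracle: exponential proposal e ~ Exp(rate 10) accepted with
        # probability exp(-e^2 / 2) gives exact draws of s* = 0 + e.
        from heckselect.gibbs import _truncnorm

        e = rng.exponential(0.1, 400_000)
        oracle = e[rng.random(e.size) < np.exp(-0.5 * e**2)]
        n = 50_000
        draws = _truncnorm(
            np.full(n, -10.0), 1.0, np.ones(n, dtype=bool), rng
        )
        assert np.isfinite(draws).all() and (draws > 0).all()
        se = math.hypot(
            draws.std() / math.sqrt(draws.size),
            oracle.std() / math.sqrt(oracle.size),
        )
        assert draws.mean() == pytest.approx(oracle.mean(), abs=4 * se)


class TestScaleConditionals:
    def test_laplace_scale_density_matches_joint_ratio(self, tiny_data, spec_factory):
        data, _ = tiny_data
        spec = spec_factory(family="laplace")
        state = random_state(data, spec, seed=21)
        # conditional of v_out[j]: invgauss on 1/v with mean tau/|coef|, shape 1
        j = 0
        tau = spec.tau1_beta if state.gamma_out[j] else spec.tau0_beta
        z = abs(state.params.beta[j]) / tau
        mu = 1.0 / z

        def logpdf_v(v):
            return float(stats.invgauss.logpdf(1.0 / v, mu / 1.0) - 2.0 * math.log(v))

        for v1, v2 in [(0.4, 1.8), (0.9, 3.0)]:
            vv1, vv2 = state.v_out.copy(), state.v_out.copy()
            vv1[j], vv2[j] = v1, v2
            ratio = _joint_with(state, data, spec, v_out=vv1) - _joint_with(
                state, data, spec, v_out=vv2
            )
            assert logpdf_v(v1) - logpdf_v(v2) == pytest.approx(
                ratio, rel=RTOL, abs=1e-8
            )

    def test_student_scale_density_matches_joint_ratio(self, tiny_data, spec_factory):
        data, _ = tiny_data
        spec = spec_factory(family="student_t")
        state = random_state(data, spec, seed=22)
        k = 1
        tau = spec.tau1_alpha if state.gamma_sel[k] else spec.tau0_alpha
        dof = spec.slab_family_selection.dof
        shape = 0.5 * (dof + 1)
        rate = 0.5 * (dof + (state.params.alpha[k] / tau) ** 2)
        for v1, v2 in [(0.5, 2.0), (1.1, 4.0)]:
            vv1, vv2 = state.v_sel.copy(), state.v_sel.copy()
            vv1[k], vv2[k] = v1, v2
            ratio = _joint_with(state, data, spec, v_sel=vv1) - _joint_with(
                state, data, spec, v_sel=vv2
            )
            lhs = stats.invgamma.logpdf(v1, shape, scale=rate) - stats.invgamma.logpdf(
                v2, shape, scale=rate
            )
            assert lhs == pytest.approx(ratio, rel=RTOL, abs=1e-8)

    def test_intercept_scale_density_matches_joint_ratio(self, tiny_data, spec_factory):
        data, _ = tiny_data
        spec = spec_factory(family="student_t")
        state = random_state(data, spec, seed=23)
        dof = spec.intercept_family_outcome.dof
        shape = 0.5 * (dof + 1)
        rate = 0.5 * (dof + state.params.beta0**2 / spec.eta_outcome)
        for v1, v2 in [(0.5, 2.0)]:
            ratio = _joint_with(state, data, spec, v0_out=v1) - _joint_with(
                state, data, spec, v0_out=v2
            )
            lhs = stats.invgamma.logpdf(v1, shape, scale=rate) - stats.invgamma.logpdf(
                v2, shape, scale=rate
            )
            assert lhs == pytest.approx(ratio, rel=RTOL, abs=1e-8)

    def test_normal_family_scales_are_unity(self, tiny_data, spec_factory, rng):
        data, _ = tiny_data
        spec = spec_factory()
        state = random_state(data, spec, seed=24)
        step_scales(state, spec, rng)
        assert (state.v_out == 1.0).all() and (state.v_sel == 1.0).all()
        assert state.v0_out == 1.0 and state.v0_sel == 1.0

    def test_laplace_inverse_mean_at_matched_coefficient(self, spec_factory, rng):
        # coef = tau => 1/v has inverse-Gaussian mean 1
        from heckselect.gibbs import _draw_scale

        fam = MixtureFamily(MixtureKind.LAPLACE)
        draws = np.array([1.0 / _draw_scale(0.5, 0.5, fam, rng) for _ in range(10**5)])
        se = draws.std() / math.sqrt(draws.size)
        assert draws.mean() == pytest.approx(1.0, abs=4 * se)

    def test_laplace_zero_coefficient_gamma_limit(self, rng):
        from heckselect.gibbs import _draw_scale

        fam = MixtureFamily(MixtureKind.LAPLACE)
        draws = np.array([_draw_scale(0.0, 0.5, fam, rng) for _ in range(10**5)])
        stat, pval = stats.kstest(draws, stats.gamma(a=0.5, scale=2.0).cdf)
        assert pval > 1e-3
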