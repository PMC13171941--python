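import numpy as np
import pytest

from heckselect import (
    LatentState,
    ModelParams,
    SimScenario,
    default_spec,
    simulate,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def tiny_data():
    """Small dataset (n=12, p=q=2) for conditional-density oracles."""
    data, truth = simulate(
        SimScenario(n=12, p=2, q=2, seed=7,
                    alpha_active=(0.5, 1.0), beta_active=(0.5, 1.0))
    )
    return data, truth


@pytest.fixture(scope="session")
def medium_data():
    """Moderate strong-signal dataset (n=500, p=q=5)."""
    data, truth = simulate(SimScenario(n=500, p=5, q=5, seed=11))
    return data, truth


def random_state(data, spec, seed):
    """A dispersed but valid latent state for conditional-ratio checks."""
    rng = np.random.default_rng(seed)
    p, q = data.n_outcome_covariates, data.n_selection_covariates
    params = ModelParams(
        alpha0=rng.normal(scale=0.5),
        alpha=rng.normal(scale=0.5, size=q),
        beta0=rng.normal(scale=0.5),
        beta=rng.normal(scale=0.5, size=p),
        rho_tilde=rng.normal(scale=0.4),
        sigma_tilde_sq=float(rng.uniform(0.5, 1.5)),
    )
    s_star = np.where(
        data.selected == 1,
        rng.uniform(0.05, 1.5, data.n),
        -rng.uniform(0.05, 1.5, data.n),
    )
    return LatentState(
        s_star=s_star,
        params=params,
        gamma_out=rng.integers(0, 2, p),
        gamma_sel=rng.integers(0, 2, q),
        v_out=rng.uniform(0.5, 2.0, p),
        v_sel=rng.uniform(0.5, 2.0, q),
        v0_out=float(rng.uniform(0.5, 2.0)),
        v0_sel=float(rng.uniform(0.5, 2.0)),
        r=float(rng.uniform(0.2, 0.8)),
    )


@pytest.fixture
def make_state():
    return random_state


@pytest.fixture
def spec_factory():
    def _make(n=500, p=2, q=2, **kw):
        return default_spec(n, p, q, **kw)

    return _make
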