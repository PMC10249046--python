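import numpy as np
import pytest

from stagessm import LaplaceMLE, LatentStates, LifeCycleParams, run_bias_study
from stagessm.simulate import ScenarioSpec, make_scenario_dataset
from stagessm.types import CovariateSet, Dataset


@pytest.fixture(scope="session")
def low_biased():
    """Low-information biased scenario: (data, true latent, true params)."""
    return make_scenario_dataset(ScenarioSpec("low", True, seed=3))


@pytest.fixture(scope="session")
def high_biased():
    """High-information biased scenario (the well-identified case)."""
    return make_scenario_dataset(ScenarioSpec("high", True, seed=1))


@pytest.fixture(scope="session")
def high_fit(high_biased):
    """Laplace-ML fit of the high-information data with psi_4 fixed at 1."""
    data, _, _ = high_biased
    est = LaplaceMLE(fix_psi={"S4": 1.0})
    est.fit(data)
    assert est.converged_
    return est.result_


# ---------------------------------------------------------------------------
# replicate simulation studies (shared by the acceptance and invariant tests)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def matched_study():
    """Unbiased data fitted with all psi correctly fixed at 1."""
    return run_bias_study(
        200, ScenarioSpec("low", False, seed=11), "fix_all", seed=101
    )


@pytest.fixture(scope="session")
def overfit_study():
    """Unbiased data fitted while estimating three bias parameters."""
    return run_bias_study(
        200, ScenarioSpec("low", False, seed=11), "estimate_psi", seed=101
    )


@pytest.fixture(scope="session")
def misspec_study():
    """Biased data fitted with bias wrongly ignored (all psi = 1)."""
    return run_bias_study(
        200, ScenarioSpec("low", True, seed=12), "fix_all", seed=102
    )


@pytest.fixture(scope="session")
def adjusted_study():
    """Biased data with the reference bias misfixed at 1 and rest free."""
    return run_bias_study(
        100, ScenarioSpec("low", True, seed=12), "estimate_psi", seed=103
    )


def tiny_model(n=3, T=4, seed=0, sigma_p=0.4, sigma_o=0.15, psi=None):
    """Small hand-built model instance for oracle comparisons."""
    rng = np.random.default_rng(seed)
    w_R = np.column_stack([np.ones(T), rng.standard_normal(T)])
    w_S = [np.column_stack([np.ones(T), rng.standard_normal(T)])
           for _ in range(n - 1)]
    cov = CovariateSet(w_R, w_S)
    surveys = [f"S{i+1}" for i in range(n)]
    psi = psi or {s: v for s, v in zip(surveys, [0.5, 1.2, 0.8, 0.3][:n])}
    params = LifeCycleParams(
        n_stages=n,
        log_N_init=6.0,
        beta_R=np.array([0.6, -0.4]),
        beta_S=[np.array([0.8, 0.7]) for _ in range(n - 1)],
        sigma_p_R=sigma_p,
        sigma_p_S=np.full(n - 1, sigma_p),
        psi=psi,
    )
    latent = LatentStates(
        rng.normal(0.5, 0.5, T), rng.normal(0.8, 0.5, (n - 1, T))
    )
    from stagessm import build_abundances

    N = build_abundances(params.log_N_init, latent)
    psi_stage = np.array([psi[s] for s in surveys])
    sig = np.full((n, T), sigma_o)
    Y = psi_stage[:, None] * N * np.exp(
        sig * rng.standard_normal((n, T)) - sig**2 / 2
    )
    data = Dataset(Y=Y, sigma_o=sig, covariates=cov, Y_init=float(np.exp(6.1)),
                   sigma_o_init=sigma_o, survey_of_stage=surveys)
    return params, latent, data
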