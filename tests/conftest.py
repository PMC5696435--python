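import numpy as np
import pytest

from bearipm.simulator import SimulationScenario, desk_scenario, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small simulated dataset reused by inference-layer tests."""
    scenario = desk_scenario(
        n_years=8, n_cmr_individuals=150, n_litters=40,
        n_reproducing_females=10, seed=3,
    )
    return simulate_dataset(scenario)


@pytest.fixture(scope="session")
def kodiak_recovery_fit():
    """Reduced-model fit to synthetic case-study data with known strong
    effects (female survival +3, salmon +0.8 on the survival logit)."""
    from bearipm.inference import McmcSettings, ModelConfig, run_mcmc
    from bearipm.kodiak import assemble_kodiak_model, generate_synthetic_kodiak

    histories, litters, cov = generate_synthetic_kodiak(
        n_individuals=90, n_years=11, seed=5,
        surv_coefs={"female": 3.0, "salmon": 0.8},
    )
    cfg = ModelConfig(
        variant="kodiak_reduced",
        mcmc=McmcSettings(n_chains=2, n_burnin=250, n_iter=250, seed=2),
    )
    model = assemble_kodiak_model(histories, litters, cov, cfg)
    samples = run_mcmc(model, cfg)
    return model, samples


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
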