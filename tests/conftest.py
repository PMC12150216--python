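import pytest
from hypothesis import HealthCheck, settings

from rbpm_cea import markov, microsim
from rbpm_cea.parameters import load_parameters

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def calibration(params):
    return markov.calibrate_base_case(params)


@pytest.fixture(scope="session")
def base_arms(params, calibration):
    rbpm = markov.evaluate_arm(params, "rbpm", calibration)
    usual = markov.evaluate_arm(params, "usual_care", calibration)
    return rbpm, usual


@pytest.fixture(scope="session")
def psa_10k(params, calibration):
    from rbpm_cea import psa

    return psa.run_psa(params, 10_000, seed=1, calibration=calibration)


@pytest.fixture(scope="session")
def microsim_200k(params, calibration):
    """200k simulated patients per arm, shared by the oracle-equivalence checks."""
    return {
        strategy: microsim.simulate_patients(params, strategy, 200_000, seed=97,
                                             calibration=calibration)
        for strategy in markov.STRATEGIES
    }
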