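import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario():
    from numadapt.synthetic import default_scenario

    return default_scenario(seed=11)


@pytest.fixture(scope="session")
def experiment(scenario):
    """One simulated experiment under the packaged adaptation scenario,
    all five conditions, shared across tests."""
    from numadapt.synthetic import simulate_experiment

    conditions = ("Baseline", "Adaptation", "Neutral", "LowNum", "HighNum")
    return simulate_experiment(scenario, seed=11, conditions=conditions)


@pytest.fixture(scope="session")
def erps(experiment):
    """participant -> condition -> trial-average ERP."""
    return {p: {c: ep.average() for c, ep in by_cond.items()}
            for p, by_cond in experiment["epochs"].items()}
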