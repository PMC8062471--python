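import numpy as np
import pytest

from stressrl import AgentParams, TaskConfig, simulate_agent


@pytest.fixture
def task_config():
    return TaskConfig(rng_seed=123)


@pytest.fixture
def s1w_params():
    return AgentParams("s1w", alpha=0.12, gamma=1.4, beta=0.1)


@pytest.fixture
def s1w_trials(s1w_params, task_config):
    """A completed 60-trial log from a moderately deterministic agent."""
    return simulate_agent(s1w_params, task_config, seed=7)


def random_params(model_name: str, rng: np.random.Generator) -> AgentParams:
    """Draw a plausible random parameter set for any of the eight models."""
    values = {
        "alpha": rng.uniform(0.02, 0.5),
        "alpha_pos": rng.uniform(0.02, 0.5),
        "alpha_neg": rng.uniform(0.02, 0.5),
        "alpha1": rng.uniform(0.02, 0.5),
        "alpha2": rng.uniform(0.02, 0.5),
        "mu": rng.uniform(0.05, 0.9),
        "kappa": rng.uniform(0.05, 0.9),
        "gamma": rng.uniform(0.3, 2.5),
        "beta": rng.uniform(0.0, 0.3),
    }
    from stressrl import MODEL_FREE_PARAMS

    return AgentParams(
        model_name, **{k: values[k] for k in MODEL_FREE_PARAMS[model_name]}
    )
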