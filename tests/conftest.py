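import numpy as np
import pytest
from hypothesis import settings

from refuge_dynamics import ModelSpec, ParamVector, scenario_presets

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def theta_median() -> ParamVector:
    """Null-model generating parameters (published posterior medians)."""
    return scenario_presets()["model1_median"].theta_true


@pytest.fixture(scope="session")
def model1() -> ModelSpec:
    return ModelSpec(1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240815)


@pytest.fixture(scope="session")
def noise_free_counts(theta_median):
    """Noise-free 26-winter series generated from the null model."""
    from dataclasses import replace

    from refuge_dynamics import generate, scenario_presets

    scenario = replace(scenario_presets()["model1_median"], noise_scale=0.0)
    return generate(scenario)
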