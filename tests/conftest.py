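import numpy as np
import pandas as pd
import pytest

from voiplan.synthetic_data import (
    DEFAULT_KAPPA,
    FACTOR_NAMES,
    PopulationConfig,
    build_design_grid,
    sample_agents,
    simulate_trials,
)
from voiplan.voi_core import AgentParams


@pytest.fixture(scope="session")
def fig3_agent() -> AgentParams:
    """The worked-example parameter set (s = 1, so scaling is neutral)."""
    return AgentParams(U_outcome=1.5, C_plan=0.8, C_info=0.1, U_leisure=0.25)


@pytest.fixture(scope="session")
def design_grid():
    return build_design_grid()


@pytest.fixture(scope="session")
def small_study(design_grid):
    """10 synthetic subjects with trials; shared across cheap tests."""
    agents = sample_agents(PopulationConfig(n_subjects=10), seed=101)
    trials = simulate_trials(agents, design_grid, DEFAULT_KAPPA, seed=102)
    return agents, trials


@pytest.fixture(scope="session")
def small_fit(small_study):
    """A quick but real hierarchical fit reused by several tests."""
    from voiplan.hierarchical_inference import ModelSpec, SamplerConfig, fit_model

    import warnings

    _, trials = small_study
    cfg = SamplerConfig(warmup=250, iterations=500, chains=2, seed=103)
    with warnings.catch_warnings():
        # short adaptation: Rhat warnings are expected and harmless here
        warnings.simplefilter("ignore", RuntimeWarning)
        post = fit_model(trials, ModelSpec("full"), cfg)
    return post


@pytest.fixture(scope="session")
def null_factor_scores():
    """Factor scores independent of everything, for 10 subjects."""
    rng = np.random.default_rng(104)
    scores = pd.DataFrame(rng.normal(size=(10, 4)), columns=list(FACTOR_NAMES))
    scores.insert(0, "subject", np.arange(10))
    return scores
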