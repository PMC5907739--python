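import numpy as np
import pytest

from picv import (
    ScenarioConfig,
    load_builtin_models,
    run_study,
    simulate_balanced_dataset,
)


@pytest.fixture(scope="session")
def models():
    return load_builtin_models()


@pytest.fixture(scope="session")
def scenario15(models):
    return models[14]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def dataset2000(models):
    """One balanced n=2000 draw from the symmetric MAF-0.5 scenario."""
    return simulate_balanced_dataset(models[14], 2000, np.random.default_rng(3))


@pytest.fixture(scope="session")
def study_200(models):
    """The scaled-down headline study: 15 scenarios, 200 paired replicates,
    n=2000, interaction model, fixed base seed.  Shared across the
    acceptance checks that read different columns of the same run."""
    configs = [
        ScenarioConfig(
            model=m,
            n=2000,
            replicates=200,
            base_seed=101,
            specs=("interaction",),
            scenario_index=i,
        )
        for i, m in enumerate(models)
    ]
    return run_study(configs)
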