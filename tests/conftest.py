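import numpy as np
import pytest

import csfstage as cs


@pytest.fixture(scope="session")
def panel():
    return cs.default_panel()


@pytest.fixture(scope="session")
def quick_settings():
    """Sampler settings small enough for the test suite, large enough to
    reach the global optimum on five-event problems."""
    return cs.SamplerSettings(n_startpoints=6, mcmc_iters=2000,
                              n_split_trials=3)


@pytest.fixture(scope="session")
def default_config():
    return cs.SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def cohort(default_config):
    return cs.simulate_cohort(default_config)


@pytest.fixture(scope="session")
def fitted(cohort, default_config, quick_settings):
    """One fully fitted pipeline on the default synthetic cohort, shared
    across tests that only need some fitted model."""
    return cs.fit_pipeline(cohort, default_config.panel,
                           settings=quick_settings, seed=100)


@pytest.fixture(scope="session")
def events(cohort, default_config, fitted):
    return cs.compute_events(cohort, default_config.panel, fitted.zscore,
                             fitted.mixtures)


def random_events(rng, n_subjects=50, n_events=5):
    """Random event-probability matrix: densities from random z under two
    fixed Gaussian components (a generic informative instance)."""
    from scipy.stats import norm

    z = rng.normal(1.0, 2.0, size=(n_subjects, n_events))
    return cs.EventProbabilityMatrix(
        np.array([f"S{i}" for i in range(n_subjects)]),
        [f"bm{j}" for j in range(n_events)],
        norm.pdf(z, 0.0, 1.0),
        norm.pdf(z, 3.0, 1.5),
    )
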