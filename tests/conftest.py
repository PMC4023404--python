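import numpy as np
import pytest

from erkshuttle.reference import load_theta_ref


@pytest.fixture(scope="session")
def theta_obs():
    """The packaged reference parameter set and observation parameters."""
    return load_theta_ref()


@pytest.fixture(scope="session")
def theta(theta_obs):
    return theta_obs[0]


@pytest.fixture(scope="session")
def obs(theta_obs):
    return theta_obs[1]


@pytest.fixture(scope="session")
def reduced_ensemble():
    """One reduced ensemble fit to the packaged synthetic dataset.

    Computed once per session (several minutes) and shared by every test that
    needs ensemble statistics.
    """
    from erkshuttle.report import ensemble_features

    return ensemble_features(seed=20, n_ensemble=200, anneal_iters=300)


@pytest.fixture(scope="session")
def noise_free_datasets(theta_obs):
    """The seven fitted designs generated with every noise CV set to zero."""
    import dataclasses

    from erkshuttle.synthetic import fitted_designs, generate_all

    theta, obs = theta_obs
    designs = [dataclasses.replace(d, measurement_cv=0.0, jitter_cv=0.0)
               for d in fitted_designs()]
    return list(generate_all(theta, designs, 2014, obs).values())
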