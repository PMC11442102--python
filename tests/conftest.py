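"""Shared fixtures: the mouse-like generating truth and synthetic beats.

Expensive artifacts (converged beats, a short posterior chain, a small
multistart fit) are session-scoped so the suite builds them once.
"""

import numpy as np
import pytest

from pvcal import (
    DEFAULT_FREE,
    ModelConstants,
    ModelParameters,
    NoiseSpec,
    simulate_to_steady_beat,
    synthesize_dataset,
)


@pytest.fixture(scope="session")
def constants():
    return ModelConstants()


@pytest.fixture(scope="session")
def truth_params():
    """The a priori mouse parameter set used as the generating truth."""
    return ModelParameters()


@pytest.fixture(scope="session")
def theta_truth_free(truth_params):
    return np.array([getattr(truth_params, n) for n in DEFAULT_FREE])


@pytest.fixture(scope="session")
def converged_beat(truth_params, constants):
    return simulate_to_steady_beat(truth_params, constants)


@pytest.fixture(scope="session")
def truth_dataset(truth_params, constants):
    _, truth = synthesize_dataset(truth_params, constants, NoiseSpec(sigma=0.0, seed=0))
    return truth


@pytest.fixture(scope="session")
def noisy_dataset(truth_params, constants):
    noisy, _ = synthesize_dataset(
        truth_params, constants, NoiseSpec(kind="iid", sigma=2.0, seed=7)
    )
    return noisy


@pytest.fixture(scope="session")
def small_fit(noisy_dataset):
    """A 6-start calibration of the noisy synthetic beat."""
    from pvcal.frequentist import multistart_fit

    return multistart_fit(noisy_dataset, n_starts=6, seed=11)


@pytest.fixture(scope="session")
def short_chain(noisy_dataset):
    """A 2,000-iteration adaptive Metropolis chain on the noisy beat."""
    from pvcal.bayesian import adaptive_metropolis_sample

    return adaptive_metropolis_sample(noisy_dataset, n_iter=2000, seed=0)


@pytest.fixture(scope="session")
def sens_matrix(truth_params, noisy_dataset):
    from pvcal import PARAM_NAMES
    from pvcal.sensitivity import local_sensitivity_matrix

    return local_sensitivity_matrix(truth_params, noisy_dataset, free_names=PARAM_NAMES)
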