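"""Shared fixtures: small synthetic datasets and one cached model fit."""

import numpy as np
import pytest

from evacc import accumulators as acc
from evacc import synthetic
from evacc.laplace_em import fit_laplace_em, simulate_batch

#: Study-condition generator parameters used across the suite.
SINGLE_GEN = {"A_acc": 0.98, "V_acc": 0.05, "Q_acc": 0.01}
IRACE_GEN = {"A_acc": 0.98, "V_acc": 0.03, "Q_acc": 0.01}
DRACE_GEN = {"A_acc": 0.95, "A_off": 0.1, "V_acc": 0.03, "V_off": -0.02,
             "Q_acc": 0.01}

FIT_INIT = {
    "single": {"A_acc": 0.95, "V_acc": 0.05, "Q_acc": 0.01},
    "independent_race": {"A_acc": 0.95, "V_acc": 0.03, "Q_acc": 0.01},
    "dependent_race": {"A_acc": 0.95, "A_off": 0.1, "V_acc": 0.03,
                       "V_off": -0.02, "Q_acc": 0.01},
}


@pytest.fixture(scope="session")
def single_spec():
    return acc.build_accumulator("single", init_values=SINGLE_GEN, seed=5)


@pytest.fixture(scope="session")
def task_trials():
    return synthetic.make_task_trials(200, seed=11)


@pytest.fixture(scope="session")
def accumulator_dataset(single_spec, task_trials):
    return synthetic.simulate_accumulator_dataset(single_spec, task_trials, seed=12)


@pytest.fixture(scope="session")
def small_fit(single_spec):
    """A modest single-accumulator fit on model-consistent data, shared by
    the fitting, scoring and comparison tests."""
    batch = simulate_batch(single_spec, 150, seed=21)
    return fit_laplace_em(
        batch, "single", init_grid=FIT_INIT["single"], n_em=8, seed=0,
        n_final_samples=100,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
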