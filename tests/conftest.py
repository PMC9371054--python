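"""Shared fixtures: all test data is generated programmatically."""

import warnings

import numpy as np
import pytest

import sdar


@pytest.fixture(scope="session")
def montage16():
    return sdar.synthetic_montage(16)


@pytest.fixture(scope="session")
def small_session():
    """12-trial subject for cheap structural tests."""
    return sdar.generate_mi_trials(n_trials=12, seed=3)


@pytest.fixture(scope="session")
def mi_session():
    """40-trial subject at the standard study conditions."""
    return sdar.generate_mi_trials(n_trials=40, seed=0, snr_db=5.0)


@pytest.fixture(scope="session")
def contaminated_session():
    """40-trial subject with a 150 uV blink artifact and its ground truth."""
    ts, truth = sdar.generate_mi_trials(n_trials=40, seed=3)
    return sdar.inject_eog(ts, truth, amplitude_uv=150.0, seed=11)


@pytest.fixture(scope="session")
def verified_cohort():
    """5-subject mixed-severity cohort with oracle-verified labels.

    Built once per test session; used by the selector and acceptance
    tests.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sdar.benchmark_cohort(seed=1)
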