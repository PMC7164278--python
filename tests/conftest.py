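"""Shared fixtures: miniature cohorts that keep the unit suite fast.

The miniature configurations shrink trial counts and durations but keep the
full signal structure (three conditions, both modalities, clone pair), so
every pipeline stage exercises the same code paths as at study scale.
"""

import logging
import warnings

import numpy as np
import pytest

from hybci import CohortConfig, PipelineConfig, generate_cohort
from hybci.pipeline import problem_data_for_subject

logging.getLogger("hybci").setLevel(logging.ERROR)


@pytest.fixture(autouse=True)
def _quiet_degenerate_warnings():
    # tiny training splits legitimately produce empty selections and
    # degenerate KDE bandwidths; they are part of what is being tested
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def tiny_mi_cohort():
    config = CohortConfig(n_subjects=3, paradigm="MI", seed=7,
                          trials_per_condition=8, trial_seconds=2.5,
                          clone_pairs=[(0, 2)])
    return generate_cohort(config)


@pytest.fixture(scope="session")
def tiny_mrwg_cohort():
    config = CohortConfig(n_subjects=2, paradigm="MRWG", seed=11,
                          trials_per_condition=6, trial_seconds=2.0)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def mi_config():
    return PipelineConfig(paradigm="MI", problem="task1-vs-baseline", seed=0)


@pytest.fixture(scope="session")
def mrwg_config():
    return PipelineConfig(paradigm="MRWG", problem="task1-vs-task2", seed=0)


@pytest.fixture(scope="session")
def tiny_mi_data(tiny_mi_cohort, mi_config):
    """Cached problem data (full 2.5 s) for each tiny-MI subject."""
    return {ds.subject_id: problem_data_for_subject(ds, mi_config)
            for ds in tiny_mi_cohort}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
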