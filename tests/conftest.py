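"""Shared fixtures.

The phantom suites and the ablation table are expensive (seconds each), so
they are built once per session and shared between the unit tests and the
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from bandseg import (
    PipelineConfig,
    default_shape_model,
    make_suite,
    run_ablation,
)

SUITE_SEED = 0
SUITE_SIZE = 20


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig().validate()


@pytest.fixture(scope="session")
def model(cfg):
    return default_shape_model(cfg)


@pytest.fixture(scope="session")
def noisy_suite():
    return make_suite(SUITE_SIZE, seed=SUITE_SEED, noisy=True)


@pytest.fixture(scope="session")
def clean_suite():
    return make_suite(SUITE_SIZE, seed=SUITE_SEED, noisy=False)


@pytest.fixture(scope="session")
def ablation_table(noisy_suite, cfg):
    return run_ablation(noisy_suite, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20261002)
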