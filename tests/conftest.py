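"""Shared fixtures: expensive cohort and DLA computations run once."""

from __future__ import annotations

import numpy as np
import pytest

from vascomplex.pipeline import cohort_fd_table, dla_block
from vascomplex.synthetic import generate_cohort


@pytest.fixture(scope="session")
def dla_frame():
    """Ten DLA replicates per geometry, whole image and halves."""
    return dla_block(n_replicates=10, rng_seed=1)


@pytest.fixture(scope="session")
def default_cohort():
    """Ten patients + ten controls at generator defaults."""
    return generate_cohort(n_patients=10, n_controls=10, rng_seed=3)


@pytest.fixture(scope="session")
def default_fd_table(default_cohort):
    return cohort_fd_table(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
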