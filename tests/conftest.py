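"""Shared fixtures: small seeded phantom cohorts and rendered bundles."""

import warnings

import numpy as np
import pytest

from nigraquant.phantom import PhantomConfig, generate_cohort, generate_feature_table


@pytest.fixture(scope="session")
def default_tables():
    """Study-sized table-level cohort (111 controls / 80 patients)."""
    return generate_feature_table(PhantomConfig(seed=42))


@pytest.fixture(scope="session")
def rendered_bundles():
    """Small noiseless image-level cohort for round-trip checks."""
    cfg = PhantomConfig(n_controls=10, n_patients=10, seed=7,
                        image_level=True, noise_sd=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2023)
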