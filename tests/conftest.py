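"""Shared fixtures: small synthetic cohorts and planted-signal matrices."""

import numpy as np
import pytest

from mirspec.preprocess import preprocess_set
from mirspec.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-sample synthetic cohort (raw spectra, covariates, truth)."""
    cfg = CohortConfig(n=40, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def processed_small_cohort(small_cohort):
    spectra, cohort, truth = small_cohort
    return preprocess_set(spectra), cohort, truth


def make_planted_matrix(seed, n=150, p=615, k=5, delta=2.0, balanced=True,
                        prevalence=23.0 / 116.0):
    """iid-noise matrix with k mean-shifted columns (total Mahalanobis delta).

    The workhorse input for selection-recovery experiments: the planted
    columns are evenly spread over the variable index range.
    """
    rng = np.random.default_rng([seed, 11])
    if balanced:
        n1 = n // 2
    else:
        n1 = int(np.floor(n * prevalence + 0.5))
    y = np.zeros(n, dtype=int)
    y[:n1] = 1
    rng.shuffle(y)
    X = rng.standard_normal((n, p))
    planted = np.linspace(50, p - 55, k).astype(int)
    X[np.ix_(y == 1, planted)] += delta / np.sqrt(k)
    return X, y, planted
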