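"""Shared fixtures: one synthetic study reused across the suite.

Expensive artifacts (parcellation, connectomes, default cohort, fitted
subtype model) are session-scoped; tests that need different simulation
settings build their own smaller cohorts.
"""

import logging

import numpy as np
import pytest

import cortsub as cs

logging.getLogger("cortsub").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def parcellation():
    return cs.generate_parcellation(100, seed=1)


@pytest.fixture(scope="session")
def connectomes(parcellation):
    return cs.generate_connectomes(parcellation, seed=2)


@pytest.fixture(scope="session")
def template(connectomes):
    return connectomes["functional"]


@pytest.fixture(scope="session")
def cohort(parcellation, template):
    config = cs.SimulationConfig(seed=11)
    table, labels, true_maps = cs.generate_cohort(config, parcellation, template)
    return table, labels, true_maps


@pytest.fixture(scope="session")
def fitted_model(cohort):
    table, _, _ = cohort
    baseline, subject_ids = table.baseline_matrix()
    X, offsets = cs.invert_thickness(baseline)
    return cs.fit_nmf(X, 2, n_restarts=10, seed=3,
                      subject_ids=subject_ids, inversion_offsets=offsets)


@pytest.fixture(scope="session")
def small_parcellation():
    return cs.generate_parcellation(40, seed=9)


def align_labels(true_labels, fitted_labels):
    """Relabel fitted subtypes to best match the planted labels."""
    true_labels = np.asarray(true_labels)
    fitted = np.asarray(fitted_labels)
    flipped = 3 - fitted  # two-subtype case
    if (fitted == true_labels).sum() >= (flipped == true_labels).sum():
        return fitted
    return flipped
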