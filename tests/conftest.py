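"""Shared fixtures: small seeded cohorts and reusable datasets.

Heavy objects are session-scoped so the expensive steps (generation,
pathway scoring, network inference) run once per test session.
"""

import numpy as np
import pytest

import icipred as ip


@pytest.fixture(scope="session")
def small_bulk_cohort():
    return ip.gen_bulk_cohort(ip.BulkManifest(
        seed=11, n_samples=80, n_genes=200, n_informative=20,
        n_planted_sets=4, effect=1.5, n_decoy_sets=12))


@pytest.fixture(scope="session")
def small_bulk_dataset(small_bulk_cohort):
    return ip.prepare_bulk_dataset(small_bulk_cohort)


@pytest.fixture(scope="session")
def small_sc_cohort():
    return ip.gen_sc_cohort(ip.SCManifest(
        seed=11, n_patients=30, n_genes=100, cells_per_patient=200))


@pytest.fixture(scope="session")
def small_sc_prep(small_sc_cohort):
    return ip.prepare_sc_dataset(small_sc_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
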